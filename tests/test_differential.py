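"""RUV group test, BH adjustment, signature selection, category summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsig.differential import (
    SignatureSet,
    category_shift_summary,
    differential_analysis,
    fdr_adjust,
    ruv_inverse_test,
    select_signatures,
)
from methsig.preprocess import betas_from_intensities, filter_probes
from methsig.simulate import SimulationConfig, simulate_intensities, simulate_study


def _bh_oracle(p):
    """Textbook step-up: sort, n*p/i, cumulative minimum from the largest."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFdrAdjust:
    def test_hand_worked_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_constant_and_singleton(self):
        assert fdr_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
        assert fdr_adjust([0.123]) == pytest.approx([0.123])
        assert fdr_adjust([]).size == 0

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 60)))
            np.testing.assert_allclose(fdr_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


def _null_study(seed, batch_strength):
    cfg = SimulationConfig(
        seed=seed, n_probes=2000, n_hyper_island=0, n_hypo_opensea=0,
        delta_beta=0.0, batch_strength=batch_strength,
    )
    study = simulate_study(cfg)
    report = filter_probes(study.cohort.intensities, study.genome.manifest)
    betas = betas_from_intensities(study.cohort.intensities, probe_ids=report.retained).values
    ctrl_ids = study.genome.manifest.loc[
        study.genome.manifest["is_negative_control"], "probe_id"
    ]
    controls = betas_from_intensities(
        study.cohort.intensities, probe_ids=pd.Index(ctrl_ids)
    ).values
    return study, betas, controls


class TestRuvInverseTest:
    def test_noise_controls_reduce_to_ols(self):
        """Structureless controls: p-values track an equal-variance t-test."""
        study, betas, controls = _null_study(seed=21, batch_strength=0.0)
        res = ruv_inverse_test(
            pd.concat([betas, controls]), study.cohort.labels, controls.index
        )
        g = (study.cohort.labels == "LTS").to_numpy()
        arr = betas.to_numpy()
        oracle = stats.ttest_ind(arr[:, g], arr[:, ~g], axis=1, equal_var=True).pvalue
        rho = stats.spearmanr(res.loc[betas.index, "p_value"], oracle).statistic
        assert rho > 0.99

    def test_null_with_batch_is_calibrated(self):
        study, betas, controls = _null_study(seed=22, batch_strength=0.04)
        res = ruv_inverse_test(
            pd.concat([betas, controls]), study.cohort.labels, controls.index
        )
        assert res.attrs["k"] >= 1  # the planted factor is found
        frac = float((res.loc[betas.index, "p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_adjustment_never_inflates_null_calls(self):
        study, betas, controls = _null_study(seed=23, batch_strength=0.05)
        combined = pd.concat([betas, controls])
        adj = ruv_inverse_test(combined, study.cohort.labels, controls.index)
        unadj = ruv_inverse_test(combined, study.cohort.labels, controls.index, k=0)
        calls_adj = (fdr_adjust(adj.loc[betas.index, "p_value"]) < 0.01).sum()
        calls_unadj = (fdr_adjust(unadj.loc[betas.index, "p_value"]) < 0.01).sum()
        assert calls_adj <= calls_unadj

    def test_permuted_labels_calibrated(self):
        """Fraction of p < 0.05 near nominal when labels are shuffled."""
        study, betas, controls = _null_study(seed=24, batch_strength=0.04)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(study.cohort.labels))
        labels = pd.Series(
            study.cohort.labels.to_numpy()[perm], index=study.cohort.labels.index
        )
        res = ruv_inverse_test(pd.concat([betas, controls]), labels, controls.index)
        frac = float((res.loc[betas.index, "p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_degenerate_probe_gets_p_one(self, study, control_betas):
        betas = pd.DataFrame(
            0.42, index=["flat1", "flat2"], columns=study.cohort.labels.index
        )
        res = ruv_inverse_test(
            pd.concat([betas, control_betas]), study.cohort.labels, control_betas.index
        )
        assert (res.loc[["flat1", "flat2"], "p_value"] == 1.0).all()

    def test_small_groups_rejected(self, control_betas):
        labels = pd.Series(["LTS", "LTS", "STS", "STS"], index=control_betas.columns[:4])
        with pytest.raises(ValueError):
            ruv_inverse_test(control_betas.iloc[:, :4], labels, control_betas.index[:20])


class TestParameterRecovery:
    def test_planted_sites_recovered_with_controlled_fdr(self):
        """>= 80% recall at q < 0.01 and empirical FDR <= 5%, across seeds."""
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_probes=2000, n_hyper_island=100,
                                   n_hypo_opensea=100)
            study = simulate_study(cfg)
            report = filter_probes(study.cohort.intensities, study.genome.manifest)
            betas = betas_from_intensities(
                study.cohort.intensities, probe_ids=report.retained
            ).values
            ctrl_ids = study.genome.manifest.loc[
                study.genome.manifest["is_negative_control"], "probe_id"
            ]
            controls = betas_from_intensities(
                study.cohort.intensities, probe_ids=pd.Index(ctrl_ids)
            ).values
            res = differential_analysis(betas, study.cohort.labels, control_betas=controls)
            truth = study.genome.truth.set_index("probe_id")
            planted_all = truth[["planted_hyper", "planted_hypo"]].any(axis=1)
            planted = planted_all.loc[res.index]
            calls = res["significant"]
            assert (calls & planted).sum() / planted_all.sum() >= 0.8
            assert (calls & ~planted).sum() / max(int(calls.sum()), 1) <= 0.05

    def test_delta_sign_convention(self, study, filtered_betas, control_betas):
        """delta is mean(LTS) - mean(STS) of the matrix handed to the test."""
        res = differential_analysis(
            filtered_betas, study.cohort.labels, control_betas=control_betas
        )
        lts = (study.cohort.labels == "LTS").to_numpy()
        manual = filtered_betas.loc[:, lts].mean(axis=1) - filtered_betas.loc[:, ~lts].mean(axis=1)
        np.testing.assert_allclose(res["delta"], manual, atol=1e-12)
        truth = study.genome.truth.set_index("probe_id")
        hyper = truth.index[truth["planted_hyper"]].intersection(res.index)
        assert (res.loc[hyper, "delta"] > 0).mean() > 0.95


class TestSelectSignatures:
    @pytest.fixture()
    def toy(self):
        results = pd.DataFrame(
            {
                "delta": [0.25, 0.2, -0.3, -0.2, 0.5],
                "significant": [True, True, True, True, False],
            },
            index=[f"p{i}" for i in range(5)],
        )
        manifest = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(5)],
                "cgi_group": ["Island", "Island", "OpenSea", "OpenSea", "Island"],
            }
        )
        return results, manifest

    def test_strict_threshold_and_membership(self, toy):
        results, manifest = toy
        sigs = select_signatures(results, manifest)
        assert sigs.hyper_island_sites == ["p0"]   # 0.2 exactly is excluded
        assert sigs.hypo_opensea_sites == ["p2"]   # -0.2 exactly is excluded

    def test_insignificant_sites_never_selected(self, toy):
        results, manifest = toy
        sigs = select_signatures(results, manifest)
        assert "p4" not in sigs.hyper_island_sites

    def test_signature_sets_must_be_disjoint(self):
        with pytest.raises(ValueError):
            SignatureSet(["a", "b"], ["b", "c"])


class TestCategoryShiftSummary:
    def test_planted_directions_recovered(self, study, filtered_betas, control_betas,
                                          annotated_manifest):
        res = differential_analysis(
            filtered_betas, study.cohort.labels, control_betas=control_betas
        )
        summary = category_shift_summary(res, annotated_manifest, by="cgi_group")
        sig = summary[summary["significant"]].set_index("category")
        assert sig.loc["Island", "median"] > 0
        assert sig.loc["OpenSea", "median"] < 0

    def test_null_generator_medians_near_zero(self):
        study, betas, controls = _null_study(seed=25, batch_strength=0.02)
        res = differential_analysis(betas, study.cohort.labels, control_betas=controls)
        from methsig.annotation import annotate_manifest

        ann = annotate_manifest(study.genome.manifest, study.genome.cgis)
        summary = category_shift_summary(res, ann, by="cgi_group")
        assert summary["median"].abs().max() < 0.02
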