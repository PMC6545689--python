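"""Differential methylation between LTS and STS with negative-control RUV.

Each probe's beta values are regressed on the group indicator (LTS = 1,
STS = 0, so a positive coefficient means hypermethylation in long-term
survivors) after adjusting for unwanted variation estimated from the
negative-control probes: the controls carry technical/batch structure but no
biology, so the leading left singular vectors of the column-centred control
matrix estimate the latent batch factors, and each target probe is then fit
by least squares on [intercept, group, factors] with a standard t test on
the group coefficient.

The number of factors defaults to a permutation-based parallel-analysis
choice: keep the singular values of the control matrix that exceed 1.1x the
median of the maximum singular values of column-permuted control matrices.
With structureless controls this selects zero factors and the test reduces
exactly to ordinary least squares; an explicit ``k`` override is exposed.

Significance is controlled by Benjamini-Hochberg FDR at q < 0.01, and the
two signature sets are the significant sites inside CpG islands with
delta > 0.2 (hypermethylated in LTS) and the significant open-sea sites with
delta < -0.2 (hypomethylated in LTS), delta being the difference of group
mean betas (LTS - STS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ruv_inverse_test",
    "fdr_adjust",
    "differential_analysis",
    "select_signatures",
    "category_shift_summary",
    "SignatureSet",
]


@dataclass
class SignatureSet:
    """The two selected site lists defining scores and the classifier."""

    hyper_island_sites: list
    hypo_opensea_sites: list

    def __post_init__(self) -> None:
        if set(self.hyper_island_sites) & set(self.hypo_opensea_sites):
            raise ValueError("signature sets must be disjoint")


def _choose_k(controls_centered: np.ndarray, max_k: int) -> int:
    """Parallel-analysis factor count on the centred control matrix."""
    s = np.linalg.svd(controls_centered, compute_uv=False)
    rng = np.random.default_rng(12345)  # internal, fixed: determinism contract
    maxima = []
    for _ in range(10):
        perm = np.array(
            [controls_centered[rng.permutation(controls_centered.shape[0]), j]
             for j in range(controls_centered.shape[1])]
        ).T
        maxima.append(np.linalg.svd(perm, compute_uv=False)[0])
    threshold = 1.1 * float(np.median(maxima))
    return int(min((s > threshold).sum(), max_k))


def ruv_inverse_test(
    betas: pd.DataFrame,
    labels: pd.Series,
    control_idx,
    k: int | None = None,
) -> pd.DataFrame:
    """Per-probe group test adjusting for control-probe-derived factors.

    Parameters
    ----------
    betas
        Probes x samples matrix containing both target and control rows.
    labels
        Sample -> group labels; "LTS" is coded 1, every other label 0.
    control_idx
        Row labels of ``betas`` that are negative-control probes.
    k
        Number of unwanted-variation components; ``None`` selects it by
        parallel analysis on the control matrix.

    Returns
    -------
    DataFrame indexed by target probe with columns ``coefficient``,
    ``statistic``, ``p_value`` and attribute-style column ``k`` metadata in
    ``.attrs``. Probes with zero variance get p = 1.
    """
    labels = labels.loc[betas.columns]
    g = (labels == "LTS").to_numpy(float)
    m = len(g)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    control_idx = pd.Index(control_idx)
    if len(control_idx) < 10:
        raise ValueError("need >= 10 control probes")
    target_idx = betas.index.difference(control_idx, sort=False)

    Y = betas.loc[target_idx].to_numpy(float).T  # m x n
    Yc = betas.loc[control_idx].to_numpy(float).T
    Yc = Yc - Yc.mean(axis=0, keepdims=True)

    max_k = m - 4
    if k is None:
        k = _choose_k(Yc, max_k)
    if k > max_k:
        raise ValueError(f"k={k} leaves too few residual degrees of freedom (m={m})")
    if k > 0:
        U, s, _ = np.linalg.svd(Yc, full_matrices=False)
        if k > (s > 1e-12).sum():
            raise ValueError("fewer informative controls than requested components")
        W = U[:, :k]
        X = np.column_stack([np.ones(m), g, W])
    else:
        X = np.column_stack([np.ones(m), g])
    p_design = X.shape[1]
    if np.linalg.matrix_rank(X) < p_design:
        raise ValueError("rank-deficient design")
    df = m - p_design

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    coeffs = H @ Y  # p_design x n
    resid = Y - X @ coeffs
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    var_g = sigma2 * XtX_inv[1, 1]
    beta_g = coeffs[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_g / np.sqrt(var_g)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance probes carry no information: p = 1 by convention
    degenerate = ~np.isfinite(t) | (Y.var(axis=0) < 1e-16)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    out = pd.DataFrame(
        {"coefficient": beta_g, "statistic": t, "p_value": p}, index=target_idx
    )
    out.attrs["k"] = int(k)
    out.attrs["df"] = int(df)
    return out


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_analysis(
    betas: pd.DataFrame,
    labels: pd.Series,
    control_betas: pd.DataFrame | None = None,
    k: int | None = None,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Full per-site differential table: delta, statistic, p, q, significance.

    ``betas`` holds target probes only; ``control_betas`` the negative
    controls (same samples). Without controls the test is plain OLS. The
    effect ``delta`` is always the difference of group mean betas
    (LTS - STS) on the matrix provided here.
    """
    labels = labels.loc[betas.columns]
    lts = labels == "LTS"
    mean_lts = betas.loc[:, lts.to_numpy()].mean(axis=1)
    mean_sts = betas.loc[:, (~lts).to_numpy()].mean(axis=1)
    if control_betas is not None:
        combined = pd.concat([betas, control_betas])
        res = ruv_inverse_test(combined, labels, control_betas.index, k=k)
        res = res.loc[betas.index]
    else:
        res = _ols_group_test(betas, labels)
    q = fdr_adjust(res["p_value"].to_numpy())
    out = pd.DataFrame(
        {
            "mean_beta_lts": mean_lts,
            "mean_beta_sts": mean_sts,
            "delta": mean_lts - mean_sts,
            "coefficient": res["coefficient"],
            "statistic": res["statistic"],
            "p_value": res["p_value"],
            "q_value": q,
            "significant": q < fdr_threshold,
        },
        index=betas.index,
    )
    out.attrs.update(res.attrs)
    return out


def _ols_group_test(betas: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Plain two-group least-squares test (no unwanted-variation adjustment)."""
    g = (labels.loc[betas.columns] == "LTS").to_numpy(float)
    m = len(g)
    X = np.column_stack([np.ones(m), g])
    XtX_inv = np.linalg.inv(X.T @ X)
    coeffs = XtX_inv @ X.T @ betas.to_numpy(float).T
    resid = betas.to_numpy(float).T - X @ coeffs
    df = m - 2
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coeffs[1] / np.sqrt(sigma2 * XtX_inv[1, 1])
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = ~np.isfinite(t) | (betas.to_numpy(float).var(axis=1) < 1e-16)
    t[bad] = 0.0
    p[bad] = 1.0
    out = pd.DataFrame(
        {"coefficient": coeffs[1], "statistic": t, "p_value": p}, index=betas.index
    )
    out.attrs["k"] = 0
    out.attrs["df"] = int(df)
    return out


def select_signatures(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    delta_threshold: float = 0.2,
) -> SignatureSet:
    """Signature sites: significant Island sites with delta strictly > 0.2
    and significant OpenSea sites with delta strictly < -0.2."""
    man = manifest.set_index("probe_id")
    group = man.loc[results.index, "cgi_group"]
    sig = results["significant"]
    hyper = results.index[
        sig & (group == "Island").to_numpy() & (results["delta"] > delta_threshold)
    ]
    hypo = results.index[
        sig & (group == "OpenSea").to_numpy() & (results["delta"] < -delta_threshold)
    ]
    return SignatureSet(list(hyper), list(hypo))


def category_shift_summary(
    results: pd.DataFrame, manifest: pd.DataFrame, by: str = "cgi_group"
) -> pd.DataFrame:
    """Median/quartile summaries of delta per category, split by significance.

    ``by`` is any manifest category column (``cgi_group``, ``cgi_category``,
    ``tss_category``); output is suitable for a violin/box rendering of the
    LTS-STS shift across genomic contexts.
    """
    man = manifest.set_index("probe_id")
    df = results.join(man[[by]])
    rows = []
    for (cat, sig), sub in df.groupby([by, "significant"]):
        if not cat:
            continue
        q1, med, q3 = np.percentile(sub["delta"], [25, 50, 75])
        rows.append(
            {
                "category": cat,
                "significant": bool(sig),
                "n": len(sub),
                "q1": q1,
                "median": med,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)
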