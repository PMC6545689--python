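"""450K-style preprocessing: detection p-values, probe filters, beta values.

The array reports, per probe and sample, a methylated intensity M and an
unmethylated intensity U measured on a bead pool. The methylation fraction
("beta value") is M / (M + U + 100); the offset of 100 stabilises the ratio
at low total intensity. Probes are screened by six rules before analysis:

i.   detection p-value > 0.01 in more than 5% of samples,
ii.  bead count < 3 in more than 5% of samples,
iii. non-CpG probes,
iv.  probes overlapping SNPs,
v.   probes whose sequence aligns to multiple genomic locations,
vi.  probes on the sex chromosomes.

All three numeric inequalities are strict. The detection p-value judges a
probe's total intensity M+U against the negative-control probes of the same
sample: under the default Gaussian background model,
p = 1 - Phi((M+U - mu_neg) / sd_neg). An empirical-rank alternative is
available for heavy-tailed backgrounds.

Intra-sample normalisation of the two probe chemistries (type I / type II)
lives in :mod:`methsig.bmiq`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityTable",
    "BetaMatrix",
    "detection_pvalue",
    "compute_beta",
    "filter_probes",
    "FILTER_RULES",
]

FILTER_RULES = [
    "detection",
    "bead_count",
    "non_cpg",
    "snp",
    "multimapped",
    "sex_chromosome",
]


@dataclass
class IntensityTable:
    """Raw probe intensities: probes x samples, plus bead counts.

    Rows cover both target probes and negative-control probes; the manifest's
    ``is_negative_control`` flag tells them apart.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    bead_counts: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.unmethylated, self.bead_counts):
            if not df.index.equals(self.methylated.index) or not df.columns.equals(
                self.methylated.columns
            ):
                raise ValueError("intensity component tables must share index/columns")
        if (self.methylated.to_numpy() < 0).any() or (self.unmethylated.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    @property
    def samples(self) -> list[str]:
        return list(self.methylated.columns)

    @property
    def probes(self) -> pd.Index:
        return self.methylated.index

    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1]."""

    values: pd.DataFrame
    normalization: str = "raw"  # {"raw", "bmiq"}

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("beta values must lie in [0, 1]")


def compute_beta(methylated, unmethylated, offset: float = 100.0):
    """Beta value M / (M + U + offset); accepts scalars or arrays."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    beta = m / (m + u + offset)
    if np.ndim(methylated) == 0 and np.ndim(unmethylated) == 0:
        return float(beta)
    return beta


def detection_pvalue(
    total_intensity,
    negative_control_totals,
    method: str = "gaussian",
):
    """Detection p-value of target total intensities against negative controls.

    Parameters
    ----------
    total_intensity
        M+U of the target probes for one sample (scalar or array).
    negative_control_totals
        Total intensities of the sample's negative-control probes (>= 10).
    method
        ``"gaussian"`` (default): p = 1 - Phi((T - mu)/sd) with mu, sd the
        control mean and standard deviation. ``"empirical"``: upper-tail rank
        of T among the controls, (# controls >= T + 1) / (n + 1).
    """
    neg = np.asarray(negative_control_totals, dtype=float)
    if neg.size < 10:
        raise ValueError(f"need >= 10 negative controls, got {neg.size}")
    t = np.asarray(total_intensity, dtype=float)
    if method == "gaussian":
        mu = neg.mean()
        sd = neg.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate negative controls: zero standard deviation")
        p = stats.norm.sf((t - mu) / sd)
    elif method == "empirical":
        p = ((neg[None, ...] >= np.atleast_1d(t)[..., None]).sum(axis=-1) + 1) / (neg.size + 1)
        p = p.reshape(np.shape(t))
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.ndim(total_intensity) == 0:
        return float(p)
    return p


def detection_pvalue_matrix(
    intensities: IntensityTable, manifest: pd.DataFrame, method: str = "gaussian"
) -> pd.DataFrame:
    """Per-(target probe, sample) detection p-values.

    Negative controls are taken from ``manifest['is_negative_control']``;
    p-values are computed per sample against that sample's controls.
    """
    ctrl_ids = manifest.loc[manifest["is_negative_control"].astype(bool), "probe_id"]
    target_ids = manifest.loc[~manifest["is_negative_control"].astype(bool), "probe_id"]
    total = intensities.total()
    ctrl_tot = total.loc[total.index.intersection(ctrl_ids)]
    tgt_tot = total.loc[total.index.intersection(target_ids)]
    out = {}
    for sample in total.columns:
        out[sample] = detection_pvalue(
            tgt_tot[sample].to_numpy(), ctrl_tot[sample].to_numpy(), method=method
        )
    return pd.DataFrame(out, index=tgt_tot.index)


@dataclass
class FilterReport:
    """Retained probes and per-rule removal accounting.

    ``removed_by_rule`` attributes each removed probe to the first firing
    rule in the order i-vi; ``fired_by_rule`` counts every firing regardless
    of attribution. Membership of the retained set does not depend on rule
    order.
    """

    retained: pd.Index
    removed_by_rule: dict = field(default_factory=dict)
    fired_by_rule: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": FILTER_RULES,
                "removed_attributed": [self.removed_by_rule.get(r, 0) for r in FILTER_RULES],
                "fired": [self.fired_by_rule.get(r, 0) for r in FILTER_RULES],
            }
        )


def filter_probes(
    intensities: IntensityTable,
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_threshold: float = 0.01,
    sample_fraction: float = 0.05,
    min_beads: int = 3,
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY"),
    detection_method: str = "gaussian",
) -> FilterReport:
    """Apply the six probe filters; returns retained target probe ids.

    A probe is removed iff any rule fires. Inequalities are strict: a probe
    fails rule i when its detection p-value exceeds ``detection_threshold``
    in strictly more than ``sample_fraction`` of samples, and rule ii when
    its bead count is strictly below ``min_beads`` in strictly more than
    ``sample_fraction`` of samples.
    """
    if len(intensities.samples) == 0:
        raise ValueError("no samples")
    man = manifest.set_index("probe_id")
    targets = man.index[~man["is_negative_control"].astype(bool)]
    targets = targets.intersection(intensities.probes)
    if detection_p is None:
        detection_p = detection_pvalue_matrix(intensities, manifest, method=detection_method)
    detection_p = detection_p.loc[targets]
    n_samples = len(intensities.samples)

    frac_fail_det = (detection_p > detection_threshold).sum(axis=1) / n_samples
    rule_i = frac_fail_det > sample_fraction
    frac_fail_bead = (intensities.bead_counts.loc[targets] < min_beads).sum(axis=1) / n_samples
    rule_ii = frac_fail_bead > sample_fraction
    rule_iii = ~man.loc[targets, "is_cpg"].astype(bool)
    rule_iv = man.loc[targets, "is_snp"].astype(bool)
    rule_v = man.loc[targets, "is_multimapped"].astype(bool)
    rule_vi = man.loc[targets, "chrom"].isin(sex_chromosomes)

    rules = dict(
        zip(FILTER_RULES, [rule_i, rule_ii, rule_iii, rule_iv, rule_v, rule_vi])
    )
    removed_any = pd.Series(False, index=targets)
    attributed: dict[str, int] = {}
    fired: dict[str, int] = {}
    for name, mask in rules.items():
        mask = mask.astype(bool)
        fired[name] = int(mask.sum())
        attributed[name] = int((mask & ~removed_any).sum())
        removed_any |= mask
    return FilterReport(
        retained=targets[~removed_any], removed_by_rule=attributed, fired_by_rule=fired
    )


def betas_from_intensities(
    intensities: IntensityTable, probe_ids=None, offset: float = 100.0
) -> BetaMatrix:
    """Beta matrix for the given probes (default: all rows)."""
    m = intensities.methylated
    u = intensities.unmethylated
    if probe_ids is not None:
        m = m.loc[probe_ids]
        u = u.loc[probe_ids]
    return BetaMatrix(pd.DataFrame(compute_beta(m.to_numpy(), u.to_numpy()),
                                   index=m.index, columns=m.columns))
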