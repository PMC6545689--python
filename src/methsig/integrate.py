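"""Integration of methylation signatures with histone marks, expression and
somatic mutations.

Three analyses relate the selected differentially-methylated site sets to
orthogonal genomic data:

* **Histone enrichment** — per histone mark, the fraction of a site set
  overlapping at least one ChIP-enriched interval, and the difference of
  that fraction between the significant and insignificant sets.
* **Expression correlation** — Pearson r between a site's beta values and
  log2(FPKM+1) of its gene across shared samples, keeping sites with
  SD(beta) > 0.1 and genes with mean FPKM > 0; a gene with several sites is
  assigned its maximum (signed) r.
* **Mutation association** — a mutation is associated with a probe site when
  it falls within +/-5 kb (inclusive); for every (site, mutated sample) pair
  the sample's beta is expressed as a Z-score against the across-sample
  distribution at that site, and the Z distributions of a site set versus a
  background set are compared by the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet

__all__ = [
    "enrichment_profile",
    "methylation_expression_correlation",
    "mutation_methylation_association",
    "methylation_signal_regression",
]

_PROPORTION_BINS = [0.0, 0.25, 0.5, 0.75, 1.0]


def _site_positions(manifest: pd.DataFrame, probe_ids) -> pd.DataFrame:
    man = manifest.set_index("probe_id")
    sub = man.loc[pd.Index(probe_ids), ["chrom", "pos"]]
    return sub


def _overlap_proportion(sites: pd.DataFrame, intervals: IntervalSet) -> float:
    if len(sites) == 0:
        raise ValueError("empty site set")
    if len(intervals) == 0:
        return 0.0
    hit = intervals.overlap_fraction(sites["chrom"].to_numpy(), sites["pos"].to_numpy())
    return float(hit.mean())


def _bin_proportion(p: float) -> str:
    """Quarter bin of an enrichment proportion, per the 4-dot-size grouping."""
    edges = _PROPORTION_BINS
    for lo, hi in zip(edges[:-1], edges[1:]):
        if p <= hi:
            return f"{lo}-{hi}"
    return "0.75-1.0"


def enrichment_profile(
    sig_sites,
    insig_sites,
    marks: dict,
    manifest: pd.DataFrame,
    aggregation: str = "union",
) -> pd.DataFrame:
    """Per-mark enrichment of a significant site set against an insignificant one.

    ``marks`` maps ``(mark, cell)`` to an :class:`IntervalSet`. With the
    default ``aggregation="union"`` a site carries a mark if any cell's
    intervals cover it; per-cell proportions are also computed and reported
    as a min-max range, since whether the source analysis pooled cells or
    averaged them is not fixed — both views are emitted.

    Returns one row per mark with the enrichment proportion of each set, the
    difference (significant - insignificant, in [-1, 1]) and the quarter bin
    of the significant set's proportion.
    """
    sig = _site_positions(manifest, sig_sites)
    insig = _site_positions(manifest, insig_sites)
    by_mark: dict[str, list] = {}
    for (mark, _cell), ivs in marks.items():
        by_mark.setdefault(mark, []).append(ivs)
    rows = []
    for mark, sets in sorted(by_mark.items()):
        union = IntervalSet(pd.concat([s.df[["chrom", "start", "end"]] for s in sets],
                                      ignore_index=True))
        per_cell_sig = [_overlap_proportion(sig, s) for s in sets]
        per_cell_insig = [_overlap_proportion(insig, s) for s in sets]
        if aggregation == "union":
            p_sig = _overlap_proportion(sig, union)
            p_insig = _overlap_proportion(insig, union)
        elif aggregation == "mean":
            p_sig = float(np.mean(per_cell_sig))
            p_insig = float(np.mean(per_cell_insig))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rows.append(
            {
                "mark": mark,
                "proportion_sig": p_sig,
                "proportion_insig": p_insig,
                "difference": p_sig - p_insig,
                "proportion_bin": _bin_proportion(p_sig),
                "per_cell_min_sig": min(per_cell_sig),
                "per_cell_max_sig": max(per_cell_sig),
            }
        )
    return pd.DataFrame(rows)


def methylation_expression_correlation(
    betas: pd.DataFrame,
    fpkm: pd.DataFrame,
    probe_gene: pd.Series,
    sd_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene maximum Pearson r between site betas and log2(FPKM+1).

    ``probe_gene`` maps probe id -> gene id (empty/missing entries are
    skipped). Sites with across-sample SD(beta) <= ``sd_threshold`` and genes
    with mean FPKM <= 0 are excluded. Requires >= 3 shared samples.

    Returns a frame indexed by gene with ``max_r`` (the signed maximum over
    the gene's surviving sites), ``n_sites`` and ``best_probe``.
    """
    shared = betas.columns.intersection(fpkm.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    b = betas[shared]
    log_expr = np.log2(fpkm[shared] + 1.0)
    mean_fpkm = fpkm[shared].mean(axis=1)
    sd_beta = b.std(axis=1, ddof=1)
    per_gene: dict[str, list[tuple[float, str]]] = {}
    for probe, gene in probe_gene.items():
        if not gene or probe not in b.index or gene not in log_expr.index:
            continue
        if sd_beta.loc[probe] <= sd_threshold or mean_fpkm.loc[gene] <= 0:
            continue
        x = b.loc[probe].to_numpy(float)
        y = log_expr.loc[gene].to_numpy(float)
        if np.std(y) == 0:
            continue
        r = float(stats.pearsonr(x, y)[0])
        per_gene.setdefault(gene, []).append((r, probe))
    rows = {}
    for gene, pairs in per_gene.items():
        best_r, best_probe = max(pairs)  # signed maximum, exactly as defined
        rows[gene] = {"max_r": best_r, "best_probe": best_probe, "n_sites": len(pairs)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def correlation_distribution_summary(
    gene_r: pd.DataFrame, focus_genes, background_genes
) -> pd.DataFrame:
    """Summaries of the per-gene r distribution for a focus vs background set."""
    rows = []
    for name, genes in (("focus", focus_genes), ("background", background_genes)):
        r = gene_r.loc[gene_r.index.intersection(pd.Index(genes)), "max_r"]
        if len(r) == 0:
            continue
        rows.append(
            {
                "set": name,
                "n_genes": len(r),
                "mean_r": r.mean(),
                "median_r": r.median(),
                "frac_negative": float((r < 0).mean()),
            }
        )
    return pd.DataFrame(rows)


def mutation_methylation_association(
    mutations: pd.DataFrame,
    betas: pd.DataFrame,
    site_set,
    background_set,
    manifest: pd.DataFrame,
    window: int = 5000,
) -> dict:
    """Z-scores of methylation in mutated samples, site set vs background.

    For each (site, sample) pair where the sample carries a mutation within
    ``window`` bases of the site (inclusive on both ends), the sample's beta
    at that site is recorded as a Z-score against the across-sample mean and
    SD at that site; a sample with several nearby mutations counts once per
    site. Sites with zero across-sample SD are dropped and counted.

    Returns a dict with the per-pair record frames for both sets, the
    two-sample KS statistic and p-value, and the dropped-pair count.
    """
    man = manifest.set_index("probe_id")
    mut_by_chrom = {
        str(c): sub.sort_values("pos").reset_index(drop=True)
        for c, sub in mutations.groupby("chrom")
    }
    site_mean = betas.mean(axis=1)
    site_sd = betas.std(axis=1, ddof=1)
    dropped = 0

    def _records(probe_ids) -> pd.DataFrame:
        nonlocal dropped
        rows = []
        for probe in probe_ids:
            if probe not in betas.index:
                continue
            chrom = str(man.loc[probe, "chrom"])
            pos = int(man.loc[probe, "pos"])
            sub = mut_by_chrom.get(chrom)
            if sub is None:
                continue
            lo = np.searchsorted(sub["pos"].to_numpy(), pos - window, side="left")
            hi = np.searchsorted(sub["pos"].to_numpy(), pos + window, side="right")
            if lo == hi:
                continue
            samples = sorted(set(sub["sample_id"].iloc[lo:hi]))
            sd = site_sd.loc[probe]
            for s in samples:
                if s not in betas.columns:
                    continue
                if sd == 0:
                    dropped += 1
                    continue
                b = betas.at[probe, s]
                rows.append(
                    {
                        "probe_id": probe,
                        "sample_id": s,
                        "beta": b,
                        "z": (b - site_mean.loc[probe]) / sd,
                    }
                )
        return pd.DataFrame(rows, columns=["probe_id", "sample_id", "beta", "z"])

    rec_site = _records(site_set)
    rec_bg = _records(background_set)
    if len(rec_site) and len(rec_bg):
        ks = stats.ks_2samp(rec_site["z"], rec_bg["z"])
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return {
        "site_records": rec_site,
        "background_records": rec_bg,
        "ks_statistic": ks_stat,
        "ks_pvalue": ks_p,
        "dropped_zero_sd": dropped,
    }


def methylation_signal_regression(beta_at_sites: pd.Series, signal: pd.Series) -> dict:
    """OLS slope of methylation on a ChIP signal over matched sites.

    A small utility mirroring the per-site methylation-versus-signal
    regressions; exercised only on synthetic signal tracks.
    """
    shared = beta_at_sites.index.intersection(signal.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 matched sites")
    res = stats.linregress(signal.loc[shared], beta_at_sites.loc[shared])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "n": int(len(shared)),
    }
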