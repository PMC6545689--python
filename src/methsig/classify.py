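"""Two-score survival-group classifier and cohort evaluation.

A sample is scored by the arithmetic mean of its beta values over the
hyper-island signature sites and, separately, over the hypo-open-sea
signature sites. It is called LTS when *both* means strictly exceed the
decision threshold (0.2), otherwise STS. Signature sites missing from a
sample's probe set are skipped and a coverage fraction is reported; with
full coverage the skipping policy cannot change a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .differential import SignatureSet

__all__ = ["SampleScore", "CohortEvaluation", "score_sample", "score_cohort",
           "evaluate_cohort", "cluster_heatmap_order"]


@dataclass
class SampleScore:
    sample_id: str
    mean_hyper: float
    mean_hypo: float
    call: str  # {"LTS", "STS"}
    coverage_hyper: float = 1.0
    coverage_hypo: float = 1.0


@dataclass
class CohortEvaluation:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def score_sample(
    beta_vector: pd.Series,
    signatures: SignatureSet,
    threshold: float = 0.2,
    sample_id: str = "",
) -> SampleScore:
    """Score one sample's betas against the two signatures.

    ``beta_vector`` is indexed by probe id. Raises ``ValueError`` when no
    site of either signature is present (uninformative sample).
    """
    scores = []
    coverages = []
    for sites in (signatures.hyper_island_sites, signatures.hypo_opensea_sites):
        sites = pd.Index(sites)
        present = sites.intersection(beta_vector.index)
        present = present[~beta_vector.loc[present].isna()]
        if len(present) == 0:
            raise ValueError(
                f"sample {sample_id or '<unnamed>'} covers no site of a signature"
            )
        scores.append(float(beta_vector.loc[present].mean()))
        coverages.append(len(present) / len(sites))
    mean_hyper, mean_hypo = scores
    call = "LTS" if (mean_hyper > threshold and mean_hypo > threshold) else "STS"
    return SampleScore(sample_id, mean_hyper, mean_hypo, call, *coverages)


def score_cohort(
    betas: pd.DataFrame, signatures: SignatureSet, threshold: float = 0.2
) -> pd.DataFrame:
    """Score every sample (column) of a beta matrix; one row per sample."""
    rows = []
    for sample in betas.columns:
        s = score_sample(betas[sample], signatures, threshold, sample_id=sample)
        rows.append(
            {
                "sample_id": s.sample_id,
                "mean_hyper": s.mean_hyper,
                "mean_hypo": s.mean_hypo,
                "call": s.call,
                "coverage_hyper": s.coverage_hyper,
                "coverage_hypo": s.coverage_hypo,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def evaluate_cohort(scores: pd.DataFrame, true_labels: pd.Series) -> CohortEvaluation:
    """Confusion counts with LTS as the positive class."""
    if len(scores) == 0:
        raise ValueError("empty cohort")
    missing = scores.index.difference(true_labels.index)
    if len(missing):
        raise ValueError(f"labels missing for samples: {list(missing)[:5]}")
    truth = true_labels.loc[scores.index]
    call = scores["call"]
    tp = int(((call == "LTS") & (truth == "LTS")).sum())
    fn = int(((call == "STS") & (truth == "LTS")).sum())
    tn = int(((call == "STS") & (truth == "STS")).sum())
    fp = int(((call == "LTS") & (truth == "STS")).sum())
    return CohortEvaluation(tp, fn, tn, fp)


def cluster_heatmap_order(betas: pd.DataFrame) -> tuple[list, list]:
    """Row (site) and column (sample) leaf orders for a heatmap rendering.

    Agglomerative clustering with Euclidean distance and complete linkage,
    on both axes. Ties follow the input order (scipy's deterministic
    behaviour), so the result is reproducible for a given matrix.
    """
    if betas.shape[0] < 2 or betas.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix")
    arr = betas.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("NaN in beta matrix")
    row_order = leaves_list(linkage(pdist(arr), method="complete"))
    col_order = leaves_list(linkage(pdist(arr.T), method="complete"))
    return (
        [betas.index[i] for i in row_order],
        [betas.columns[j] for j in col_order],
    )


def plot_score_scatter(scores: pd.DataFrame, threshold: float = 0.2, path=None):
    """Scatter of the two signature scores with the decision lines.

    Optional convenience rendering; requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for call, sub in scores.groupby("call"):
        ax.scatter(sub["mean_hyper"], sub["mean_hypo"], label=call, s=18)
    ax.axvline(threshold, ls="--", c="grey")
    ax.axhline(threshold, ls="--", c="grey")
    ax.set_xlabel("mean beta, hyper-island signature")
    ax.set_ylabel("mean beta, hypo-open-sea signature")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
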