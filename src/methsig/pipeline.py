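"""Stage orchestration over plain TSV/BED artifacts in a run directory.

Each stage reads the declared outputs of the previous stages from the run
directory, writes its own outputs there, and records a JSON run manifest
(package/library versions, seed, parameters, input digests). All artifacts
are plain text, so any stage can be re-run or inspected independently, and
a fixed seed reproduces byte-identical files.

Stage order: simulate -> preprocess -> diff -> integrate -> go -> classify.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_manifest
from .bmiq import bmiq_normalize_matrix
from .classify import evaluate_cohort, score_cohort
from .differential import (
    SignatureSet,
    category_shift_summary,
    differential_analysis,
    select_signatures,
)
from .go_enrichment import GeneUniverse, weighted_resampling_test
from .integrate import (
    correlation_distribution_summary,
    enrichment_profile,
    methylation_expression_correlation,
    mutation_methylation_association,
)
from .intervals import IntervalSet
from .preprocess import (
    IntensityTable,
    betas_from_intensities,
    detection_pvalue_matrix,
    filter_probes,
)
from .simulate import HISTONE_MARKS, SimulationConfig, simulate_study

log = logging.getLogger("methsig")

_FLOAT_FMT = "%.8g"
STAGES = ["simulate", "preprocess", "diff", "integrate", "go", "classify"]


class MissingArtifactError(FileNotFoundError):
    """An upstream stage output is missing; the message names the stage."""


@dataclass
class RunConfig:
    """All thresholds and knobs of the pipeline, with study defaults.

    Numeric defaults are the printed analysis parameters: detection p 0.01
    in > 5% of samples, bead count 3, site FDR 0.01, signature and
    classifier thresholds 0.2, mutation window 5 kb, 1000 GO resamples.
    """

    outdir: str = "run"
    seed: int = 0
    detection_threshold: float = 0.01
    sample_fraction: float = 0.05
    min_beads: int = 3
    fdr_threshold: float = 0.01
    delta_threshold: float = 0.2
    classifier_threshold: float = 0.2
    mutation_window: int = 5000
    go_resamples: int = 1000
    go_fdr_threshold: float = 0.05
    ruv_k: int | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("detection_threshold", "sample_fraction", "fdr_threshold",
                     "delta_threshold", "classifier_threshold", "go_fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_beads <= 0 or self.mutation_window <= 0 or self.go_resamples <= 0:
            raise ValueError("min_beads, mutation_window and go_resamples must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_run_manifest(outdir: Path, stage: str, config: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "methsig_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
        },
        "inputs": {p.name: _digest(p) for p in sorted(set(inputs))},
    }
    with open(outdir / f"run_manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _require(outdir: Path, name: str, produced_by: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise MissingArtifactError(
            f"missing {name}: run the `{produced_by}` stage first"
        )
    return path


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# --------------------------------------------------------------------------
def run_simulate(config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config.simulation_config())
    study.write(out)
    _write_run_manifest(out, "simulate", config, [])
    log.info("simulate: wrote synthetic study to %s", out)


def run_preprocess(config: RunConfig) -> None:
    out = Path(config.outdir)
    man_path = _require(out, "manifest.tsv", "simulate")
    meth_p = _require(out, "intensities_meth.tsv", "simulate")
    unmeth_p = _require(out, "intensities_unmeth.tsv", "simulate")
    beads_p = _require(out, "bead_counts.tsv", "simulate")
    manifest = pd.read_csv(man_path, sep="\t", keep_default_na=False)
    intens = IntensityTable(_read_matrix(meth_p), _read_matrix(unmeth_p), _read_matrix(beads_p))
    det_p = detection_pvalue_matrix(intens, manifest)
    report = filter_probes(
        intens,
        manifest,
        detection_p=det_p,
        detection_threshold=config.detection_threshold,
        sample_fraction=config.sample_fraction,
        min_beads=config.min_beads,
    )
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    raw = betas_from_intensities(intens, probe_ids=report.retained)
    raw.values.to_csv(out / "beta_raw.tsv", sep="\t", float_format=_FLOAT_FMT,
                      index_label="probe_id")
    assay = manifest.set_index("probe_id")["assay_type"]
    norm, qc = bmiq_normalize_matrix(raw.values, assay)
    norm.to_csv(out / "beta_bmiq.tsv", sep="\t", float_format=_FLOAT_FMT,
                index_label="probe_id")
    qc.to_csv(out / "bmiq_qc.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    ctrl_ids = manifest.loc[manifest["is_negative_control"].astype(bool), "probe_id"]
    ctrl_beta = betas_from_intensities(intens, probe_ids=pd.Index(ctrl_ids))
    ctrl_beta.values.to_csv(out / "beta_controls.tsv", sep="\t", float_format=_FLOAT_FMT,
                            index_label="probe_id")
    _write_run_manifest(out, "preprocess", config, [man_path, meth_p, unmeth_p, beads_p])
    log.info(
        "preprocess: retained %d probes (%s)",
        len(report.retained),
        ", ".join(f"{k}={v}" for k, v in report.removed_by_rule.items() if v),
    )


def run_diff(config: RunConfig) -> None:
    out = Path(config.outdir)
    beta_p = _require(out, "beta_bmiq.tsv", "preprocess")
    ctrl_p = _require(out, "beta_controls.tsv", "preprocess")
    labels_p = _require(out, "labels.tsv", "simulate")
    man_p = _require(out, "manifest.tsv", "simulate")
    cgi_p = _require(out, "cgi.bed", "simulate")
    genes_p = _require(out, "genes.tsv", "simulate")
    betas = _read_matrix(beta_p)
    controls = _read_matrix(ctrl_p)
    labels = pd.read_csv(labels_p, sep="\t", index_col=0)["group"]
    manifest = pd.read_csv(man_p, sep="\t", keep_default_na=False)
    cgis = IntervalSet.read_bed(cgi_p)
    genes = pd.read_csv(genes_p, sep="\t")
    annotated = annotate_manifest(manifest, cgis, genes)
    annotated.to_csv(out / "manifest_annotated.tsv", sep="\t", index=False)
    results = differential_analysis(
        betas, labels, control_betas=controls, k=config.ruv_k,
        fdr_threshold=config.fdr_threshold,
    )
    full = results.join(
        annotated.set_index("probe_id")[["chrom", "pos", "cgi_category", "cgi_group",
                                         "tss_category", "gene"]]
    )
    full.to_csv(out / "differential.tsv", sep="\t", float_format=_FLOAT_FMT,
                index_label="probe_id")
    sigs = select_signatures(results, annotated, delta_threshold=config.delta_threshold)
    ann = annotated.set_index("probe_id")
    for name, sites in (("hyper_island", sigs.hyper_island_sites),
                        ("hypo_opensea", sigs.hypo_opensea_sites)):
        pd.Series(sites, name="probe_id").to_csv(out / f"signature_{name}.tsv",
                                                 sep="\t", index=False)
        bed = ann.loc[sites, ["chrom", "pos"]].assign(end=lambda d: d["pos"] + 1)
        bed.to_csv(out / f"signature_{name}.bed", sep="\t", header=False,
                   columns=["chrom", "pos", "end"], index=False)
    for by in ("cgi_category", "cgi_group", "tss_category"):
        category_shift_summary(results, annotated, by=by).to_csv(
            out / f"category_shift_{by}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    _write_run_manifest(out, "diff", config,
                        [beta_p, ctrl_p, labels_p, man_p, cgi_p, genes_p])
    log.info(
        "diff: %d significant sites (k=%d), signatures %d hyper / %d hypo",
        int(results["significant"].sum()), results.attrs.get("k", -1),
        len(sigs.hyper_island_sites), len(sigs.hypo_opensea_sites),
    )


def _load_signatures(out: Path) -> SignatureSet:
    hyper_p = _require(out, "signature_hyper_island.tsv", "diff")
    hypo_p = _require(out, "signature_hypo_opensea.tsv", "diff")

    def _read(p):
        df = pd.read_csv(p, sep="\t")
        return df["probe_id"].tolist() if len(df) else []

    return SignatureSet(_read(hyper_p), _read(hypo_p))


def run_integrate(config: RunConfig) -> None:
    out = Path(config.outdir)
    diff_p = _require(out, "differential.tsv", "diff")
    man_p = _require(out, "manifest_annotated.tsv", "diff")
    beta_p = _require(out, "beta_bmiq.tsv", "preprocess")
    fpkm_p = _require(out, "fpkm.tsv", "simulate")
    mut_p = _require(out, "mutations.tsv", "simulate")
    diff = pd.read_csv(diff_p, sep="\t", index_col=0, keep_default_na=False,
                       na_values=[""])
    diff["significant"] = diff["significant"].astype(bool)
    manifest = pd.read_csv(man_p, sep="\t", keep_default_na=False)
    betas = _read_matrix(beta_p)
    fpkm = _read_matrix(fpkm_p)
    mutations = pd.read_csv(mut_p, sep="\t")
    sigs = _load_signatures(out)

    marks = {}
    for mark in HISTONE_MARKS:
        for bed in sorted(out.glob(f"histone_{mark}_*.bed")):
            cell = bed.stem.split("_")[-1]
            marks[(mark, cell)] = IntervalSet.read_bed(bed)
    insig_island = diff.index[(~diff["significant"]) & (diff["cgi_group"] == "Island")]
    insig_opensea = diff.index[(~diff["significant"]) & (diff["cgi_group"] == "OpenSea")]
    if marks:
        frames = []
        for name, sig_set, insig_set in (
            ("hyper_island", sigs.hyper_island_sites, insig_island),
            ("hypo_opensea", sigs.hypo_opensea_sites, insig_opensea),
        ):
            if len(sig_set) and len(insig_set):
                prof = enrichment_profile(sig_set, insig_set, marks, manifest)
                prof.insert(0, "signature", name)
                frames.append(prof)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "histone_enrichment.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )

    probe_gene = manifest.set_index("probe_id")["gene"]
    gene_r = methylation_expression_correlation(betas, fpkm, probe_gene)
    gene_r.to_csv(out / "gene_correlation.tsv", sep="\t", float_format=_FLOAT_FMT)
    hyper_genes = set(probe_gene.reindex(sigs.hyper_island_sites).dropna()) - {""}
    insig_genes = set(probe_gene.reindex(insig_island).dropna()) - {""}
    corr_summary = correlation_distribution_summary(gene_r, hyper_genes, insig_genes)
    corr_summary.to_csv(out / "correlation_summary.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)

    assoc = mutation_methylation_association(
        mutations, betas, sigs.hypo_opensea_sites, list(insig_opensea), manifest,
        window=config.mutation_window,
    )
    assoc["site_records"].to_csv(out / "mutation_z_site.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    assoc["background_records"].to_csv(out / "mutation_z_background.tsv", sep="\t",
                                       index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [{"ks_statistic": assoc["ks_statistic"], "ks_pvalue": assoc["ks_pvalue"],
          "n_site_pairs": len(assoc["site_records"]),
          "n_background_pairs": len(assoc["background_records"]),
          "dropped_zero_sd": assoc["dropped_zero_sd"]}]
    ).to_csv(out / "mutation_ks.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_run_manifest(out, "integrate", config,
                        [diff_p, man_p, beta_p, fpkm_p, mut_p])
    log.info("integrate: mutation KS p = %.3g", assoc["ks_pvalue"])


def run_go(config: RunConfig) -> None:
    out = Path(config.outdir)
    man_p = _require(out, "manifest_annotated.tsv", "diff")
    terms_p = _require(out, "go_terms.tsv", "simulate")
    desc_p = _require(out, "go_descriptions.tsv", "simulate")
    manifest = pd.read_csv(man_p, sep="\t", keep_default_na=False)
    terms_df = pd.read_csv(terms_p, sep="\t")
    desc = dict(pd.read_csv(desc_p, sep="\t").itertuples(index=False, name=None))
    terms = {t: set(sub["gene_id"]) for t, sub in terms_df.groupby("term_id")}
    universe = GeneUniverse.from_manifest(manifest, terms, desc)
    sigs = _load_signatures(out)
    probe_gene = manifest.set_index("probe_id")["gene"]
    test_genes = (
        set(probe_gene.reindex(sigs.hyper_island_sites).dropna()) - {""}
    ) & set(universe.weights.index)
    if not test_genes:
        log.warning("go: no signature genes in universe; skipping")
        return
    rows = weighted_resampling_test(
        test_genes, universe, n_resamples=config.go_resamples, seed=config.seed,
        fdr_threshold=config.go_fdr_threshold,
    )
    rows.to_csv(out / "go_enrichment.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_run_manifest(out, "go", config, [man_p, terms_p, desc_p])
    log.info("go: %d terms significant at q < %g",
             int(rows["significant"].sum()), config.go_fdr_threshold)


def run_classify(config: RunConfig) -> None:
    out = Path(config.outdir)
    beta_p = _require(out, "beta_bmiq.tsv", "preprocess")
    labels_p = _require(out, "labels.tsv", "simulate")
    betas = _read_matrix(beta_p)
    labels = pd.read_csv(labels_p, sep="\t", index_col=0)["group"]
    sigs = _load_signatures(out)
    scores = score_cohort(betas, sigs, threshold=config.classifier_threshold)
    scores.to_csv(out / "scores.tsv", sep="\t", float_format=_FLOAT_FMT)
    ev = evaluate_cohort(scores, labels)
    pd.DataFrame(
        [{"tp": ev.tp, "fn": ev.fn, "tn": ev.tn, "fp": ev.fp,
          "sensitivity": ev.sensitivity, "specificity": ev.specificity}]
    ).to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_run_manifest(out, "classify", config, [beta_p, labels_p])
    log.info("classify: sensitivity %.3f, specificity %.3f",
             ev.sensitivity, ev.specificity)


_RUNNERS = {
    "simulate": run_simulate,
    "preprocess": run_preprocess,
    "diff": run_diff,
    "integrate": run_integrate,
    "go": run_go,
    "classify": run_classify,
}


def run(stage: str, config: RunConfig) -> None:
    """Run one stage, or every stage in order with ``stage="all"``."""
    if stage == "all":
        for s in STAGES:
            _RUNNERS[s](config)
        return
    if stage not in _RUNNERS:
        raise ValueError(f"unknown stage {stage!r}; one of {STAGES + ['all']}")
    _RUNNERS[stage](config)
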