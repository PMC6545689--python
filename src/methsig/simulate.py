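"""Synthetic methylation study generator.

Emulates, from a single seed, the statistical structure of a two-group 450K
methylation study contrasting long-term (LTS) and short-term (STS)
glioblastoma survivors: a small genome with CpG islands and genes, an array
manifest with two assay chemistries and negative-control probes, raw
intensities with bead counts and planted QC failures, a latent batch factor
shared by negative controls and a subset of target probes, planted
hypermethylation (in LTS) inside CpG islands and hypomethylation in the open
sea, promoter methylation negatively coupled to gene expression, somatic
mutations preferentially placed near high-methylation open-sea sites, and
histone-mark intervals co-located with the planted site classes (H3K27ac
over hyper-island sites, H3K9me3 over hypo-open-sea sites).

Design choices:

* Per-(probe, sample) betas are drawn from Beta distributions parameterised
  by (mean, precision), so values respect [0, 1] by construction.
* The type-II chemistry is emulated as an affine compression of the
  biological beta toward 0.5, applied before intensities are formed, so the
  BMIQ step has genuine work to do.
* A single latent batch factor loads on every negative control and on a
  configurable fraction of target probes, giving the RUV step identifiable
  unwanted variation.

Identical ``SimulationConfig`` (including seed) reproduces byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .preprocess import IntensityTable

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "SimulatedCohort",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_intensities",
    "simulate_expression_and_mutations",
    "simulate_study",
    "HISTONE_MARKS",
]

HISTONE_MARKS = [
    "H2az",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K79me2",
    "H3K9ac",
    "H3K9me1",
    "H3K9me3",
    "H4K20me1",
]
_CELLS = ["cellA", "cellB", "cellC"]


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the discovery design being emulated: 17 LTS vs 12 STS
    samples, 5000 probes with 250 hypermethylated sites planted inside CpG
    islands and 250 hypomethylated sites planted in the open sea, a planted
    group difference of 0.25 in mean beta, a ~72% type-II probe fraction and
    600 negative controls (450K-like), and modest batch structure.
    """

    seed: int = 0
    n_lts: int = 17
    n_sts: int = 12
    n_probes: int = 5000
    frac_type2: float = 0.72
    n_neg_controls: int = 600
    n_hyper_island: int = 250
    n_hypo_opensea: int = 250
    delta_beta: float = 0.25
    batch_strength: float = 0.04
    batch_frac: float = 0.30
    type2_shift: float = 0.4
    beta_precision: float = 100.0
    bead_fail_frac: float = 0.01
    detect_fail_frac: float = 0.01
    frac_non_cpg: float = 0.02
    frac_snp: float = 0.02
    frac_multimap: float = 0.02
    frac_sex: float = 0.03
    mutation_rate: float = 30.0
    mutation_coupling: float = 0.8
    mutations_per_coupled_site: float = 2.0
    expression_coupling: float = 0.7
    expression_noise: float = 0.5
    n_background_genes: int = 300
    n_chromosomes: int = 5
    chrom_size: int = 10_000_000
    sex_chrom_size: int = 3_000_000

    def __post_init__(self) -> None:
        if self.n_hyper_island + self.n_hypo_opensea > self.n_probes:
            raise ValueError("planted sites exceed n_probes")
        if self.n_probes > 0 and not 0 <= self.delta_beta < 1:
            raise ValueError("delta_beta must lie in [0, 1)")
        if not 0 <= self.type2_shift < 1:
            raise ValueError("type2_shift must lie in [0, 1)")
        for f in ("frac_type2", "batch_frac", "bead_fail_frac", "detect_fail_frac"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ValueError(f"{f} must lie in [0, 1]")


@dataclass
class SimulatedGenome:
    chrom_sizes: dict
    cgis: IntervalSet
    genes: pd.DataFrame
    histone_marks: dict  # (mark, cell) -> IntervalSet
    manifest: pd.DataFrame
    truth: pd.DataFrame
    gene_truth: pd.DataFrame
    go_terms: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["term_id", "gene_id"]))
    go_descriptions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["term_id", "description"]))


@dataclass
class SimulatedCohort:
    intensities: IntensityTable
    labels: pd.Series  # sample -> {"LTS","STS"}
    beta_true: pd.DataFrame  # biological betas, target probes only


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: SimulatedGenome
    cohort: SimulatedCohort
    fpkm: pd.DataFrame
    mutations: pd.DataFrame

    def new_cohort(self, seed: int, n_lts: int | None = None, n_sts: int | None = None) -> SimulatedCohort:
        """Fresh samples on the same array design and planted truth."""
        return simulate_intensities(self.config, self.genome, seed=seed, n_lts=n_lts, n_sts=n_sts)

    def write(self, outdir) -> None:
        write_study(self, outdir)


def _autosomes(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build genome, CGIs, genes, histone marks, manifest and truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    autosomes = _autosomes(config)
    chrom_sizes = {c: config.chrom_size for c in autosomes}
    chrom_sizes["chrX"] = config.sex_chrom_size
    chrom_sizes["chrY"] = config.sex_chrom_size

    empty_manifest_cols = [
        "probe_id", "chrom", "pos", "assay_type",
        "is_negative_control", "is_cpg", "is_snp", "is_multimapped",
    ]
    if config.n_probes == 0:
        empty = pd.DataFrame(columns=empty_manifest_cols)
        return SimulatedGenome(
            chrom_sizes,
            IntervalSet.from_intervals([]),
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand", "tss",
                                  "first_exon_start", "first_exon_end"]),
            {},
            empty,
            pd.DataFrame(columns=["probe_id", "planted_hyper", "planted_hypo",
                                  "mutation_coupled", "batch_loaded",
                                  "bad_detection", "bad_beads"]),
            pd.DataFrame(columns=["gene_id", "expression_coupled", "coupled_probe"]),
        )

    # --- CpG islands on a regular anchor grid with jittered lengths -------
    n_cgi = max(config.n_probes // 8, config.n_hyper_island + 20,
                config.n_hypo_opensea + 20, 20)
    per_chrom = int(np.ceil(n_cgi / len(autosomes)))
    spacing = config.chrom_size // (per_chrom + 1)
    max_len = 1400
    if spacing // 2 - max_len // 2 <= 4200:
        raise ValueError(
            "infeasible counts: CGI spacing too tight to leave open sea "
            f"(spacing {spacing} for {n_cgi} CGIs)"
        )
    cgi_rows = []
    for ci in range(n_cgi):
        chrom = autosomes[ci % len(autosomes)]
        anchor = (ci // len(autosomes) + 1) * spacing
        length = int(rng.integers(400, max_len))
        start = anchor - length // 2
        cgi_rows.append((chrom, start, start + length, f"CGI{ci:05d}"))
    cgis = IntervalSet(pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "name"]))
    cgi_df = cgis.df

    # --- probes ----------------------------------------------------------
    order = rng.permutation(n_cgi)
    hyper_cgis = order[: config.n_hyper_island]
    probes: list[tuple[str, int]] = []
    planted_hyper_idx = []
    planted_hypo_idx = []
    for ci in hyper_cgis:
        row = cgi_df.iloc[ci]
        planted_hyper_idx.append(len(probes))
        probes.append((row["chrom"], int((row["start"] + row["end"]) // 2)))
    hypo_cgis = order[config.n_hyper_island: config.n_hyper_island + config.n_hypo_opensea]
    for ci in hypo_cgis:
        row = cgi_df.iloc[ci]
        planted_hypo_idx.append(len(probes))
        # midway to the next anchor: > 4 kb from every CGI by construction
        probes.append((row["chrom"], int((row["start"] + row["end"]) // 2 + spacing // 2)))

    n_sex = int(round(config.frac_sex * config.n_probes))
    n_rest = config.n_probes - len(probes) - n_sex
    if n_rest < 0:
        raise ValueError("infeasible counts: planted + sex probes exceed n_probes")
    sex_idx = []
    for i in range(n_sex):
        chrom = "chrX" if i % 2 == 0 else "chrY"
        sex_idx.append(len(probes))
        probes.append((chrom, int(rng.integers(10_000, config.sex_chrom_size - 10_000))))
    rest_idx = []
    kinds = rng.random(n_rest)
    for k in kinds:
        rest_idx.append(len(probes))
        if k < 0.30:  # background island probe
            row = cgi_df.iloc[int(rng.integers(0, n_cgi))]
            pos = int(rng.integers(row["start"], row["end"]))
            probes.append((row["chrom"], pos))
        elif k < 0.50:  # shore/shelf flank
            row = cgi_df.iloc[int(rng.integers(0, n_cgi))]
            off = int(rng.integers(1, 4001)) * (1 if rng.random() < 0.5 else -1)
            pos = int(row["end"] - 1 + off if off > 0 else row["start"] + off)
            probes.append((row["chrom"], max(pos, 0)))
        else:  # uniform background
            chrom = autosomes[int(rng.integers(0, len(autosomes)))]
            probes.append((chrom, int(rng.integers(10_000, config.chrom_size - 10_000))))

    n_t = len(probes)
    probe_ids = [f"cg{i:06d}" for i in range(n_t)]
    chroms = np.array([p[0] for p in probes], dtype=object)
    positions = np.array([p[1] for p in probes], dtype=np.int64)
    assay_type = np.where(rng.random(n_t) < config.frac_type2, "II", "I")

    planted_hyper = np.zeros(n_t, bool)
    planted_hyper[planted_hyper_idx] = True
    planted_hypo = np.zeros(n_t, bool)
    planted_hypo[planted_hypo_idx] = True
    planted = planted_hyper | planted_hypo

    def _flag(frac: float, exclude: np.ndarray) -> np.ndarray:
        out = np.zeros(n_t, bool)
        pool = np.flatnonzero(~exclude)
        k = min(int(round(frac * n_t)), pool.size)
        if k:
            out[rng.choice(pool, size=k, replace=False)] = True
        return out

    taken = planted.copy()
    taken[sex_idx] = True
    is_snp = _flag(config.frac_snp, taken)
    is_multimap = _flag(config.frac_multimap, taken | is_snp)
    non_cpg = _flag(config.frac_non_cpg, taken | is_snp | is_multimap)
    taken2 = taken | is_snp | is_multimap | non_cpg
    bad_detection = _flag(max(0.005, config.detect_fail_frac / 2), taken2)
    bad_beads = _flag(max(0.005, config.bead_fail_frac / 2), taken2 | bad_detection)

    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": positions,
            "assay_type": assay_type,
            "is_negative_control": False,
            "is_cpg": ~non_cpg,
            "is_snp": is_snp,
            "is_multimapped": is_multimap,
        }
    )
    controls = pd.DataFrame(
        {
            "probe_id": [f"negctl{i:04d}" for i in range(config.n_neg_controls)],
            "chrom": "",
            "pos": -1,
            "assay_type": "II",
            "is_negative_control": True,
            "is_cpg": False,
            "is_snp": False,
            "is_multimapped": False,
        }
    )
    manifest = pd.concat([manifest, controls], ignore_index=True)

    batch_loaded = np.zeros(n_t, bool)
    n_loaded = int(round(config.batch_frac * n_t))
    if n_loaded:
        batch_loaded[rng.choice(n_t, size=n_loaded, replace=False)] = True
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "planted_hyper": planted_hyper,
            "planted_hypo": planted_hypo,
            "mutation_coupled": planted_hypo,
            "batch_loaded": batch_loaded,
            "bad_detection": bad_detection,
            "bad_beads": bad_beads,
        }
    )

    # --- genes: one promoter gene per hyper site + background genes -------
    gene_rows = []
    gene_truth_rows = []
    for gi, pi in enumerate(planted_hyper_idx):
        tss = int(positions[pi] + 100)  # probe sits 100 bp upstream of a + TSS
        gid = f"GENE{gi:05d}"
        gene_rows.append(
            (gid, chroms[pi], tss, min(tss + 20_000, config.chrom_size), "+",
             tss, tss, tss + 300)
        )
        gene_truth_rows.append((gid, True, probe_ids[pi]))
    for gi in range(config.n_background_genes):
        chrom = autosomes[int(rng.integers(0, len(autosomes)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(10_000, config.chrom_size - 60_000))
        length = int(rng.integers(5_000, 50_000))
        end = start + length
        gid = f"GENE{gi + len(planted_hyper_idx):05d}"
        if strand == "+":
            tss, fe = start, (start, start + int(rng.integers(200, 500)))
        else:
            tss, fe = end - 1, (end - int(rng.integers(200, 500)), end)
        gene_rows.append((gid, chrom, start, end, strand, tss, fe[0], fe[1]))
        gene_truth_rows.append((gid, False, ""))
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "tss",
                 "first_exon_start", "first_exon_end"],
    )
    gene_truth = pd.DataFrame(
        gene_truth_rows, columns=["gene_id", "expression_coupled", "coupled_probe"]
    )

    # --- histone marks: planted co-location + random background ----------
    histone = {}
    n_bg_iv = max(20, n_t // 40)
    for mark in HISTONE_MARKS:
        for cell in _CELLS:
            rows = []
            if mark == "H3K27ac":
                focus = planted_hyper_idx
            elif mark == "H3K9me3":
                focus = planted_hypo_idx
            else:
                focus = []
            for pi in focus:
                if rng.random() < 0.85:
                    rows.append((chroms[pi], max(0, positions[pi] - 500), positions[pi] + 500))
            for _ in range(n_bg_iv):
                chrom = autosomes[int(rng.integers(0, len(autosomes)))]
                start = int(rng.integers(0, config.chrom_size - 3000))
                rows.append((chrom, start, start + int(rng.integers(800, 2000))))
            histone[(mark, cell)] = IntervalSet(
                pd.DataFrame(rows, columns=["chrom", "start", "end"])
            )

    # --- synthetic biological-process terms over the gene universe -------
    all_genes = genes["gene_id"].to_numpy(object)
    coupled_genes = gene_truth.loc[gene_truth["expression_coupled"], "gene_id"].to_numpy(object)
    term_rows = []
    desc_rows = []
    if len(all_genes):
        if len(coupled_genes):
            members = list(
                rng.choice(coupled_genes, size=max(1, int(0.8 * len(coupled_genes))), replace=False)
            ) + list(rng.choice(all_genes, size=min(10, len(all_genes)), replace=False))
            term_rows += [("BP00000", g) for g in sorted(set(members))]
            desc_rows.append(("BP00000", "planted term enriched in promoter-coupled genes"))
        for ti in range(1, 31):
            size = int(rng.integers(10, 40))
            members = rng.choice(all_genes, size=min(size, len(all_genes)), replace=False)
            term_rows += [(f"BP{ti:05d}", g) for g in sorted(set(members))]
            desc_rows.append((f"BP{ti:05d}", f"synthetic biological process {ti}"))
    go_terms = pd.DataFrame(term_rows, columns=["term_id", "gene_id"])
    go_desc = pd.DataFrame(desc_rows, columns=["term_id", "description"])

    return SimulatedGenome(
        chrom_sizes, cgis, genes, histone, manifest, truth, gene_truth, go_terms, go_desc
    )


def simulate_intensities(
    config: SimulationConfig,
    genome: SimulatedGenome,
    seed: int | None = None,
    n_lts: int | None = None,
    n_sts: int | None = None,
) -> SimulatedCohort:
    """Draw a cohort of raw intensities on the given array design.

    ``seed`` defaults to a stream derived from ``config.seed``; passing a
    different seed yields an independent cohort on the same design (used for
    held-out classifier validation).
    """
    seed = config.seed if seed is None else seed
    n_lts = config.n_lts if n_lts is None else n_lts
    n_sts = config.n_sts if n_sts is None else n_sts
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    m = n_lts + n_sts
    samples = [f"LTS{i + 1:02d}" for i in range(n_lts)] + [
        f"STS{i + 1:02d}" for i in range(n_sts)
    ]
    labels = pd.Series(["LTS"] * n_lts + ["STS"] * n_sts, index=samples, name="group")
    is_lts = np.array([1.0] * n_lts + [0.0] * n_sts)

    man = genome.manifest
    tgt = man[~man["is_negative_control"]].reset_index(drop=True)
    n_t = len(tgt)
    truth = genome.truth
    kappa = config.beta_precision

    if n_t:
        hyper = truth["planted_hyper"].to_numpy()
        hypo = truth["planted_hypo"].to_numpy()
        in_island = np.zeros(n_t, bool)
        for chrom, sub in tgt.groupby("chrom", sort=False):
            if chrom and not genome.cgis.is_empty(str(chrom)):
                in_island[sub.index] = genome.cgis.contains(
                    str(chrom), sub["pos"].to_numpy()
                )
        base = np.where(
            in_island, rng.beta(1.5, 8.0, n_t), rng.beta(5.0, 2.2, n_t)
        )
        base = np.clip(base, 0.03, 0.90)
        base[hyper] = rng.uniform(0.03, 0.12, hyper.sum())
        base[hypo] = rng.uniform(0.55, 0.80, hypo.sum())
        plant = np.zeros(n_t)
        plant[hyper] = config.delta_beta
        plant[hypo] = -config.delta_beta

        u_batch = rng.normal(size=m)
        loading = np.zeros(n_t)
        loaded = truth["batch_loaded"].to_numpy()
        loading[loaded] = rng.normal(0.0, config.batch_strength, loaded.sum())

        mean = base[:, None] + plant[:, None] * is_lts[None, :] + loading[:, None] * u_batch[None, :]
        mean = np.clip(mean, 0.02, 0.93)
        beta_true = rng.beta(mean * kappa, (1 - mean) * kappa)

        obs = beta_true.copy()
        t2 = (tgt["assay_type"] == "II").to_numpy()
        obs[t2] = 0.5 + (1 - config.type2_shift) * (obs[t2] - 0.5)
        obs = np.clip(obs, 0.01, 0.90)

        total = np.exp(rng.normal(np.log(3000.0), 0.25, size=(n_t, m)))
        total = np.clip(total, 1500.0, None)
        # planted QC failures: background-level intensities / low bead counts
        planted_mask = hyper | hypo
        fail_det = rng.random((n_t, m)) < config.detect_fail_frac
        fail_det[planted_mask] = False
        bad_det = truth["bad_detection"].to_numpy()
        n_fail_cols = max(2, int(np.ceil(0.2 * m)))
        for i in np.flatnonzero(bad_det):
            fail_det[i, rng.choice(m, size=n_fail_cols, replace=False)] = True

        meth = obs * (total + 100.0)
        unmeth = total - meth
        bg = np.clip(rng.normal(120.0, 15.0, size=(n_t, m, 2)), 1.0, None)
        meth = np.where(fail_det, bg[:, :, 0], meth)
        unmeth = np.where(fail_det, bg[:, :, 1], unmeth)

        beads = rng.poisson(15.0, size=(n_t, m))
        fail_bead = rng.random((n_t, m)) < config.bead_fail_frac
        fail_bead[planted_mask] = False
        bad_bead = truth["bad_beads"].to_numpy()
        for i in np.flatnonzero(bad_bead):
            fail_bead[i, rng.choice(m, size=n_fail_cols, replace=False)] = True
        beads = np.where(fail_bead, rng.integers(0, 3, size=(n_t, m)), beads)
    else:
        u_batch = rng.normal(size=m)
        beta_true = np.zeros((0, m))
        meth = np.zeros((0, m))
        unmeth = np.zeros((0, m))
        beads = np.zeros((0, m), dtype=int)

    # negative controls: background intensities carrying the batch factor
    n_c = config.n_neg_controls
    if n_c:
        base_c = np.clip(rng.normal(0.35, 0.02, n_c), 0.1, 0.5)
        load_c = rng.normal(0.0, 1.5 * config.batch_strength, n_c)
        mean_c = np.clip(base_c[:, None] + load_c[:, None] * u_batch[None, :], 0.05, 0.58)
        beta_c = np.clip(rng.beta(mean_c * kappa, (1 - mean_c) * kappa), 0.02, 0.60)
        total_c = np.clip(rng.normal(240.0, 25.0, size=(n_c, m)), 170.0, None)
        meth_c = beta_c * (total_c + 100.0)
        unmeth_c = total_c - meth_c
        beads_c = rng.poisson(15.0, size=(n_c, m))
    else:
        meth_c = np.zeros((0, m))
        unmeth_c = np.zeros((0, m))
        beads_c = np.zeros((0, m), dtype=int)

    all_ids = man["probe_id"].tolist()
    meth_df = pd.DataFrame(np.vstack([meth, meth_c]), index=all_ids, columns=samples)
    unmeth_df = pd.DataFrame(np.vstack([unmeth, unmeth_c]), index=all_ids, columns=samples)
    beads_df = pd.DataFrame(
        np.vstack([beads, beads_c]).astype(int), index=all_ids, columns=samples
    )
    beta_true_df = pd.DataFrame(beta_true, index=tgt["probe_id"].tolist(), columns=samples)
    return SimulatedCohort(
        IntensityTable(meth_df, unmeth_df, beads_df), labels, beta_true_df
    )


def simulate_expression_and_mutations(
    config: SimulationConfig,
    genome: SimulatedGenome,
    betas: pd.DataFrame,
    labels: pd.Series,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table and MAF-like mutation table coupled to the given betas.

    Expression of genes whose promoter hosts a planted hyper-island probe is
    negatively coupled to that probe's beta: log2(FPKM+1) = 6 - 4c*beta +
    noise with c = ``expression_coupling``; with c = 1 and zero noise the
    relation is exactly affine decreasing. Mutations are placed within
    +/-4 kb of mutation-coupled (planted hypo-open-sea) sites, preferentially
    in samples where that site's beta is high, on top of a uniform
    background of ``mutation_rate`` mutations per sample.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    samples = list(betas.columns)
    m = len(samples)
    autosomes = _autosomes(config)

    # --- expression ------------------------------------------------------
    rows = {}
    coupled = genome.gene_truth[genome.gene_truth["expression_coupled"]]
    for gid, probe in zip(coupled["gene_id"], coupled["coupled_probe"]):
        if probe not in betas.index:
            continue
        b = betas.loc[probe].to_numpy(float)
        log_expr = 6.0 - 4.0 * config.expression_coupling * b
        if config.expression_noise > 0:
            log_expr = log_expr + rng.normal(0.0, config.expression_noise, m)
        rows[gid] = np.clip(2.0**log_expr - 1.0, 0.0, None)
    background = genome.gene_truth[~genome.gene_truth["expression_coupled"]]
    for i, gid in enumerate(background["gene_id"]):
        if i % 10 == 0:  # silent genes exercise the mean-FPKM filter
            rows[gid] = np.zeros(m)
        else:
            mu = rng.normal(4.0, 1.0)
            rows[gid] = np.clip(2.0 ** (mu + rng.normal(0.0, 1.0, m)) - 1.0, 0.0, None)
    fpkm = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    fpkm.index.name = "gene_id"

    # --- mutations -------------------------------------------------------
    mut_rows = []
    bases = np.array(list("ACGT"))
    if config.mutation_rate > 0 and autosomes:
        for s in samples:
            k = rng.poisson(config.mutation_rate)
            for _ in range(k):
                chrom = autosomes[int(rng.integers(0, len(autosomes)))]
                pos = int(rng.integers(0, config.chrom_size))
                ref, alt = rng.choice(bases, size=2, replace=False)
                mut_rows.append((s, chrom, pos, ref, alt))
        man = genome.manifest.set_index("probe_id")
        coupled_sites = genome.truth.loc[genome.truth["mutation_coupled"], "probe_id"]
        for probe in coupled_sites:
            if probe in betas.index:
                b = betas.loc[probe].to_numpy(float)
                sd = b.std()
                z = (b - b.mean()) / sd if sd > 0 else np.zeros(m)
                # coupling = 0 -> uniform sample choice (mutation-prone region
                # with no methylation preference)
                w = np.exp(5.0 * config.mutation_coupling * z)
                w /= w.sum()
                n_mut = rng.poisson(config.mutations_per_coupled_site)
                chrom = str(man.loc[probe, "chrom"])
                pos0 = int(man.loc[probe, "pos"])
                for _ in range(n_mut):
                    s = samples[int(rng.choice(m, p=w))]
                    pos = pos0 + int(rng.integers(-4000, 4001))
                    ref, alt = rng.choice(bases, size=2, replace=False)
                    mut_rows.append((s, chrom, max(pos, 0), ref, alt))
    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    )
    return fpkm, mutations


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full synthetic study: genome, discovery cohort, expression, mutations."""
    genome = simulate_genome(config)
    cohort = simulate_intensities(config, genome)
    # couple expression/mutations to the biological betas: chemistry
    # compression is a measurement artifact, not biology
    fpkm, mutations = simulate_expression_and_mutations(
        config, genome, cohort.beta_true, cohort.labels
    )
    return SimulatedStudy(config, genome, cohort, fpkm, mutations)


_FLOAT_FMT = "%.8g"


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write every table of the study as plain TSV/BED under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = study.genome
    g.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    g.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    g.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    g.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    g.go_terms.to_csv(out / "go_terms.tsv", sep="\t", index=False)
    g.go_descriptions.to_csv(out / "go_descriptions.tsv", sep="\t", index=False)
    g.cgis.write_bed(out / "cgi.bed")
    for (mark, cell), ivs in g.histone_marks.items():
        ivs.write_bed(out / f"histone_{mark}_{cell}.bed")
    c = study.cohort
    c.intensities.methylated.to_csv(
        out / "intensities_meth.tsv", sep="\t", float_format=_FLOAT_FMT, index_label="probe_id"
    )
    c.intensities.unmethylated.to_csv(
        out / "intensities_unmeth.tsv", sep="\t", float_format=_FLOAT_FMT, index_label="probe_id"
    )
    c.intensities.bead_counts.to_csv(out / "bead_counts.tsv", sep="\t", index_label="probe_id")
    c.labels.rename_axis("sample_id").to_frame().to_csv(out / "labels.tsv", sep="\t")
    c.beta_true.to_csv(
        out / "beta_true.tsv", sep="\t", float_format=_FLOAT_FMT, index_label="probe_id"
    )
    study.fpkm.to_csv(out / "fpkm.tsv", sep="\t", float_format=_FLOAT_FMT)
    study.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    import yaml

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(study.config), fh, sort_keys=True)
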