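"""Histone/expression/mutation integration and the two-score classifier.

Relates the discovered signatures to histone marks, gene expression and
somatic mutations, then classifies an independently simulated cohort by the
rule: LTS iff both signature mean betas exceed 0.2.
"""

import pandas as pd

from methsig.annotation import annotate_manifest
from methsig.bmiq import bmiq_normalize_matrix
from methsig.classify import evaluate_cohort, score_cohort
from methsig.differential import differential_analysis, select_signatures
from methsig.go_enrichment import GeneUniverse, weighted_resampling_test
from methsig.integrate import (
    enrichment_profile,
    methylation_expression_correlation,
    mutation_methylation_association,
)
from methsig.preprocess import betas_from_intensities, filter_probes
from methsig.simulate import SimulationConfig, simulate_study

cfg = SimulationConfig(seed=1, n_probes=2000, n_hyper_island=100, n_hypo_opensea=100)
study = simulate_study(cfg)
report = filter_probes(study.cohort.intensities, study.genome.manifest)
betas = betas_from_intensities(study.cohort.intensities, probe_ids=report.retained).values
assay = study.genome.manifest.set_index("probe_id")["assay_type"]
norm, _ = bmiq_normalize_matrix(betas, assay)
ctrl_ids = study.genome.manifest.loc[
    study.genome.manifest["is_negative_control"], "probe_id"]
controls = betas_from_intensities(study.cohort.intensities,
                                  probe_ids=pd.Index(ctrl_ids)).values
res = differential_analysis(norm, study.cohort.labels, control_betas=controls)
ann = annotate_manifest(study.genome.manifest, study.genome.cgis, study.genome.genes)
sigs = select_signatures(res, ann)
group = ann.set_index("probe_id").loc[res.index, "cgi_group"]
insig_island = list(res.index[~res["significant"] & (group == "Island").to_numpy()])
insig_sea = list(res.index[~res["significant"] & (group == "OpenSea").to_numpy()])

# histone marks: which marks co-locate with each signature?
prof = enrichment_profile(sigs.hyper_island_sites, insig_island,
                          study.genome.histone_marks, ann).set_index("mark")
print(f"H3K27ac enrichment difference at hyper-island sites: "
      f"{prof.loc['H3K27ac', 'difference']:+.3f}")
print("(fraction of signature sites in H3K27ac regions minus the same for "
      "insignificant island sites)")

# expression: promoter methylation represses transcription
probe_gene = ann.set_index("probe_id")["gene"]
gene_r = methylation_expression_correlation(norm, study.fpkm, probe_gene)
coupled = study.genome.gene_truth.loc[
    study.genome.gene_truth["expression_coupled"], "gene_id"]
r = gene_r.loc[gene_r.index.intersection(coupled), "max_r"]
print(f"\npromoter-coupled genes with negative methylation-expression r: "
      f"{100 * (r < 0).mean():.0f}% of {len(r)}")

# mutations: are mutated samples unusually methylated at hypo sites?
assoc = mutation_methylation_association(
    study.mutations, norm, sigs.hypo_opensea_sites, insig_sea, study.genome.manifest)
print(f"mutation-methylation KS p (hypo sites vs background): "
      f"{assoc['ks_pvalue']:.2e}")

# GO enrichment, corrected for per-gene probe counts
terms = {t: set(s["gene_id"]) for t, s in study.genome.go_terms.groupby("term_id")}
uni = GeneUniverse.from_manifest(ann, terms)
test_genes = (set(probe_gene.reindex(sigs.hyper_island_sites).dropna()) - {""}
              ) & set(uni.weights.index)
go = weighted_resampling_test(test_genes, uni, n_resamples=1000, seed=1)
top = go.iloc[0]
print(f"top GO term: {top['term_id']} (q = {top['q_value']:.3g}, "
      f"{top['n_intersect']}/{top['n_total']} genes)")

# classify an unseen cohort with the discovery signatures
cohort = study.new_cohort(seed=99, n_lts=12, n_sts=39)
vrep = filter_probes(cohort.intensities, study.genome.manifest)
vraw = betas_from_intensities(cohort.intensities, probe_ids=vrep.retained).values
vnorm, _ = bmiq_normalize_matrix(vraw, assay)
ev = evaluate_cohort(score_cohort(vnorm, sigs), cohort.labels)
print(f"\nheld-out cohort (12 LTS / 39 STS): sensitivity "
      f"{100 * ev.sensitivity:.0f}%, specificity {100 * ev.specificity:.0f}%")
print("(a sample is called LTS when both signature mean betas exceed 0.2)")
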