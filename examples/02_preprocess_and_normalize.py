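"""Probe filtering, beta values and BMIQ chemistry normalisation.

Shows the six filter rules firing on planted QC failures, and how BMIQ
shrinks the distribution gap between type-I and type-II probes.
"""

from scipy import stats

from methsig.bmiq import bmiq_normalize_matrix
from methsig.preprocess import betas_from_intensities, filter_probes
from methsig.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1, n_probes=2000,
                                        n_hyper_island=100, n_hypo_opensea=100))
report = filter_probes(study.cohort.intensities, study.genome.manifest)
print("per-rule removals (attributed in rule order):")
print(report.to_frame().to_string(index=False))
print(f"retained {len(report.retained)} probes")

betas = betas_from_intensities(study.cohort.intensities, probe_ids=report.retained).values
assay = study.genome.manifest.set_index("probe_id")["assay_type"]
norm, qc = bmiq_normalize_matrix(betas, assay)

at = assay.loc[betas.index].to_numpy()
sample = betas.columns[0]
before = stats.ks_2samp(betas[sample][at == "I"], betas[sample][at == "II"]).statistic
after = stats.ks_2samp(norm[sample][at == "I"], norm[sample][at == "II"]).statistic
print(f"\n{sample}: type-I vs type-II Kolmogorov distance "
      f"{before:.3f} -> {after:.3f} after BMIQ")
print("(the type-II chemistry compresses betas toward 0.5; BMIQ undoes it)")
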