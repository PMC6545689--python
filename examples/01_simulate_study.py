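"""Build a seeded synthetic methylation study and look at its structure.

The generator emulates a two-group 450K study (17 long-term vs 12
short-term glioblastoma survivors) with hypermethylation planted inside CpG
islands and hypomethylation planted in the open sea.
"""

from methsig.simulate import SimulationConfig, simulate_study

config = SimulationConfig(seed=1, n_probes=2000, n_hyper_island=100, n_hypo_opensea=100)
study = simulate_study(config)

manifest = study.genome.manifest
targets = manifest[~manifest["is_negative_control"]]
print(f"probes: {len(targets)} targets + {manifest['is_negative_control'].sum()} negative controls")
print(f"samples: {(study.cohort.labels == 'LTS').sum()} LTS, {(study.cohort.labels == 'STS').sum()} STS")
print(f"CpG islands: {len(study.genome.cgis)}, genes: {len(study.genome.genes)}")
print(f"mutations: {len(study.mutations)} across {study.mutations['sample_id'].nunique()} samples")

truth = study.genome.truth
lts = (study.cohort.labels == "LTS").to_numpy()
bt = study.cohort.beta_true
delta = bt.loc[:, lts].mean(axis=1) - bt.loc[:, ~lts].mean(axis=1)
hyper = truth.loc[truth["planted_hyper"], "probe_id"]
hypo = truth.loc[truth["planted_hypo"], "probe_id"]
print(f"mean LTS-STS delta at planted hyper-island sites: {delta.loc[hyper].mean():+.3f}")
print(f"mean LTS-STS delta at planted hypo-open-sea sites: {delta.loc[hypo].mean():+.3f}")
print("(both should sit near the planted effect of +/-0.25)")
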