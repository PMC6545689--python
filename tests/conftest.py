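"""Shared fixtures: one modest synthetic study reused across test modules."""

import pandas as pd
import pytest

from methsig import annotate_manifest, betas_from_intensities, filter_probes
from methsig.bmiq import bmiq_normalize_matrix
from methsig.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_probes=2000, n_hyper_island=100, n_hypo_opensea=100)


@pytest.fixture(scope="session")
def study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def filtered_betas(study):
    """Raw betas over the probes surviving the six filters."""
    report = filter_probes(study.cohort.intensities, study.genome.manifest)
    return betas_from_intensities(study.cohort.intensities, probe_ids=report.retained).values


@pytest.fixture(scope="session")
def control_betas(study):
    man = study.genome.manifest
    ctrl_ids = man.loc[man["is_negative_control"], "probe_id"]
    return betas_from_intensities(study.cohort.intensities, probe_ids=pd.Index(ctrl_ids)).values


@pytest.fixture(scope="session")
def normalized_betas(study, filtered_betas):
    assay = study.genome.manifest.set_index("probe_id")["assay_type"]
    norm, _ = bmiq_normalize_matrix(filtered_betas, assay)
    return norm


@pytest.fixture(scope="session")
def annotated_manifest(study):
    return annotate_manifest(study.genome.manifest, study.genome.cgis, study.genome.genes)
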