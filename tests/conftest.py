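"""Shared fixtures: tiny hand-built matrices and one simulated study.

The simulated study (session-scoped) runs the expensive stages once:
generation, biochemical classification, filtering, log10, per-cohort
differential tables. Everything is seeded, so test outcomes are stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import csfpanel as cp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

SIM_SEED = 0


def make_matrix(values, sample_ids=None, scale=cp.Scale.LINEAR, protein_ids=None):
    """IntensityMatrix from a 2-D array/list with NaN as missing."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    pids = protein_ids or [f"P{i:03d}" for i in range(n)]
    sids = sample_ids or [f"s{j}" for j in range(m)]
    recs = [cp.ProteinRecord(protein_id=p) for p in pids]
    frame = pd.DataFrame(arr, index=pd.Index(pids, name="protein_id"), columns=sids)
    return cp.IntensityMatrix(proteins=recs, values=frame, scale=scale)


@pytest.fixture(scope="session")
def sim_config():
    return cp.default_study_config(seed=SIM_SEED)


@pytest.fixture(scope="session")
def sim_study(sim_config):
    return cp.simulate_study(sim_config)


@pytest.fixture(scope="session")
def sim_bundle(sim_study):
    return sim_study[0]


@pytest.fixture(scope="session")
def sim_truth(sim_study):
    return sim_study[1]


@pytest.fixture(scope="session")
def sim_labels(sim_bundle):
    return cp.labels_as_series(cp.classify_cohort(sim_bundle.metadata))


@pytest.fixture(scope="session")
def sim_log_bundle(sim_bundle):
    filtered = cp.filter_min_observations(sim_bundle.matrix, 20)
    return cp.StudyBundle(
        matrix=cp.log10_transform(filtered), metadata=sim_bundle.metadata
    )


@pytest.fixture(scope="session")
def sim_diff_tables(sim_log_bundle, sim_labels):
    return cp.cohort_differential_tables(
        sim_log_bundle, sim_labels, cp.AnalysisConfig(n_permutations=250), seed=SIM_SEED
    )
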