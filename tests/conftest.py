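"""Shared fixtures: hand-built toys and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

import msinfluence as mi
from msinfluence.data import LONG_COLUMNS
from msinfluence.graph import TransitionGraph


@pytest.fixture(scope="session")
def two_state_graph():
    """Minimal graph: 1 -> 2, state 2 absorbing (a plain survival model)."""
    return TransitionGraph(2, ((1, 2),), frozenset({2}))


def make_g1_dataset(graph, durations, statuses, z, ids=None):
    """One-transition dataset with a single scalar covariate ``z``."""
    n = len(durations)
    ids = ids or [f"A{i}" for i in range(n)]
    table = pd.DataFrame({
        "id": ids, "from": 1, "to": 2, "trans": 1,
        "Tstart": 0.0, "Tstop": np.asarray(durations, dtype=float),
        "status": list(statuses), "z": np.asarray(z, dtype=float),
    })
    return mi.MultistateDataset(graph, table, ["z"])


@pytest.fixture
def toy_g1(two_state_graph):
    """3 patients, exits {2, 5, 9}, events for the first two, z = {1, 0, 2}."""
    return make_g1_dataset(two_state_graph, [2.0, 5.0, 9.0], [1, 1, 0],
                           [1.0, 0.0, 2.0], ids=["A", "B", "C"])


@pytest.fixture
def tied_g1(two_state_graph):
    """4 records with two tied event times (Breslow convention toy)."""
    return make_g1_dataset(two_state_graph, [3.0, 3.0, 7.0, 8.0], [1, 1, 0, 1],
                           [0.5, -0.5, 1.0, 0.0])


@pytest.fixture(scope="session")
def small_cohort():
    """Clean simulated figure-1 cohort, n = 60."""
    data, truth = mi.simulate_cohort(mi.SimulationConfig(n=60, seed=7))
    return data, truth


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    data, _ = small_cohort
    return mi.fit(data)


def brute_force_loglik(beta, data):
    """Independent product-form evaluation of the log partial likelihood.

    Direct enumeration over event records with explicit risk-set loops;
    shares no code with the vectorized implementation.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    tab = data.table
    covs = data.covariates
    total = 0.0
    for _, row in tab[tab["status"] == 1].iterrows():
        g, t = row["trans"], row["Tstop"] - row["Tstart"]
        z = np.array([row[c] for c in covs], dtype=float)
        denom = 0.0
        for _, other in tab[tab["trans"] == g].iterrows():
            dur = other["Tstop"] - other["Tstart"]
            if 0.0 < t <= dur:
                zo = np.array([other[c] for c in covs], dtype=float)
                denom += np.exp(float(zo @ beta))
        total += float(z @ beta) - np.log(denom)
    return total
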