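import numpy as np
import pandas as pd
import pytest

import chromnet as cn


@pytest.fixture(scope="session")
def small_params():
    """Reduced-size study conditions for fast unit tests."""
    return cn.SimulationParams(n_promoters=1200, seed=7)


@pytest.fixture(scope="session")
def fixture_pair(small_params):
    """One truth network observed in conditions A and B."""
    return cn.make_fixture_pair(small_params)


@pytest.fixture(scope="session")
def standardized(fixture_pair):
    """Condition-A matrix taken through the full preprocessing chain."""
    _, sm_a, _ = fixture_pair
    return cn.preprocess(sm_a)


def make_raw_matrix(counts: dict, roles: dict) -> cn.SignalMatrix:
    """Raw-count SignalMatrix from plain dicts of equal-length columns."""
    data = pd.DataFrame({k: np.asarray(v) for k, v in counts.items()})
    data.index = [f"p{i}" for i in range(len(data))]
    return cn.SignalMatrix(data=data, roles=roles, state="raw_counts")


def make_standardized(columns: dict, roles: dict) -> cn.SignalMatrix:
    """Directly build a matrix in the standardized state (test shortcut)."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    data.index = [f"p{i}" for i in range(len(data))]
    return cn.SignalMatrix(data=data, roles=dict(roles), state="standardized")
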