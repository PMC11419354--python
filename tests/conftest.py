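import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def chain_dag():
    from bapdeconf import DirectedAcyclicGraph

    return DirectedAcyclicGraph(["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def diamond_dag():
    from bapdeconf import DirectedAcyclicGraph

    return DirectedAcyclicGraph(
        ["a", "b", "c", "d"],
        [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")],
    )


def random_dag_case(p, n_edges, seed):
    """Shared helper: a random DAG drawn by the package's own generator."""
    from bapdeconf import random_dag

    return random_dag(p, n_edges, seed)


@pytest.fixture
def gaussian_frame(rng):
    """Correlated 4-variable Gaussian sample for partial-correlation checks."""
    n = 300
    L = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.6, 0.8, 0.0, 0.0],
            [0.3, 0.4, 0.87, 0.0],
            [0.2, 0.1, 0.5, 0.84],
        ]
    )
    X = rng.standard_normal((n, 4)) @ L.T
    return pd.DataFrame(X, columns=list("wxyz"))
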