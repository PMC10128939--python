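import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from exomatch import cluster, constraints

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_universe(symbols, seed=0):
    """A valid constraint universe over the given symbols, metrics random."""
    symbols = list(symbols)
    p = len(symbols)
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "transcript_id": [f"T{i:05d}" for i in range(1, p + 1)],
            "oe_lof": rng.uniform(0.0, 2.0, p),
            "oe_mis": rng.uniform(0.2, 1.8, p),
            "oe_syn": rng.uniform(0.4, 1.6, p),
            "lof_z": rng.normal(1.0, 2.0, p),
            "mis_z": rng.normal(0.8, 1.5, p),
            "syn_z": rng.normal(0.0, 1.3, p),
            "pli": rng.uniform(0.0, 1.0, p),
            "genomic_length": rng.integers(2_000, 200_000, p).astype(float),
            "transcript_length": rng.integers(300, 8_000, p).astype(float),
            "n_exons": rng.integers(1, 60, p).astype(float),
        },
        index=pd.Index(symbols, name="gene_symbol"),
    )
    return constraints.ConstraintUniverse(frame)


@pytest.fixture
def universe_factory():
    return make_universe


@pytest.fixture(scope="session")
def small_universe():
    """A 60-gene universe with arbitrary (but valid) metrics."""
    return make_universe([f"G{i:03d}" for i in range(1, 61)], seed=3)


@pytest.fixture(scope="session")
def sim_universe():
    """Synthetic 5,000-gene universe with the published metric correlations."""
    return constraints.simulate_constraints(5000, seed=7)


@pytest.fixture(scope="session")
def sim_tree(sim_universe):
    return cluster.build_tree(cluster.normalize_metrics(sim_universe))


@pytest.fixture(scope="session")
def sim_partition(sim_tree):
    """The fixed gene partition used by the simulation study (see docs)."""
    return cluster.cut_tree(sim_tree, 0.02)
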