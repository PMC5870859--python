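import numpy as np
import pytest
from hypothesis import settings

from orthopred import fixtures

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    """A 600-compound clustered drug-like library (deterministic)."""
    return fixtures.generate_library(fixtures.FixtureSpec(pool_size=600, seed=7))


@pytest.fixture(scope="session")
def tables():
    """Synthetic study tables for 4 targets with a planted 5% conflict rate."""
    spec = fixtures.FixtureSpec(n_targets=4, pool_size=400, conflict_rate=0.05,
                                seed=3)
    return fixtures.generate_bioactivity_tables(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
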