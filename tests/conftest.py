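import numpy as np
import pytest

import bedbench as bb


@pytest.fixture(scope="session")
def table2():
    return bb.load_fixture("table2")


@pytest.fixture(scope="session")
def regions():
    return bb.load_fixture("regions")


@pytest.fixture(scope="session")
def synthetic_table():
    """A default-condition synthetic 50-state table (fixed seed)."""
    return bb.generate(bb.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_table():
    """A synthetic table with zero noise: bed rates sit exactly on the model surface."""
    return bb.generate(bb.GeneratorConfig(seed=42, sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_covariate_csv(path, frame):
    """Write a covariate table CSV in the canonical schema."""
    frame.to_csv(path, index=False, float_format="%.17g")
    return path
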