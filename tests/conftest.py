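import logging

import numpy as np
import pandas as pd
import pytest

from fidlme import ChainConfig, LMEDesign, build_design, generate, get_scenario

# chain-mixing warnings are expected on tiny designs; keep test output clean
logging.getLogger("fidlme.sampler").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def example1_design():
    """One fixed dataset from the random-slope scenario (m=10, n_i=2)."""
    design, truth = generate(get_scenario("example1"), np.random.default_rng(20240901))
    return design, truth


@pytest.fixture(scope="session")
def example2_design():
    """One fixed dataset from the null-intercept scenario (q=2)."""
    design, truth = generate(get_scenario("example2"), np.random.default_rng(20240902))
    return design, truth


@pytest.fixture
def tiny_design():
    """Hand-built balanced design: m=3, n_i=2, p=1, q=1."""
    rng = np.random.default_rng(7)
    z = rng.standard_normal(6)
    y = 0.5 + 0.8 * z + rng.standard_normal(6) * 0.5
    table = pd.DataFrame({"y": y, "g": [1, 1, 2, 2, 3, 3], "z": z})
    return build_design(table, response="y", group="g", random=("z",))


@pytest.fixture
def short_config():
    return ChainConfig(chain_length=400, warmup=100, thin=1, seed=11)


def make_design(y, X, Z, sizes):
    idx = np.repeat(np.arange(len(sizes)), sizes)
    return LMEDesign(y=y, X=X, Z=Z, group_sizes=np.asarray(sizes), group_index=idx)


@pytest.fixture
def design_factory():
    return make_design
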