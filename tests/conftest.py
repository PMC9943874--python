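import numpy as np
import pytest

from pubevolve import ModelParams, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_lab():
    return make_fixture("three-lab")


@pytest.fixture
def two_lab_tournament():
    return make_fixture("two-lab-tournament")


@pytest.fixture
def static_params():
    """Homogeneous no-evolution population: W=0.8, e=75, r=0, b=0.1."""
    _, params = make_fixture("static-fdr")
    return params


@pytest.fixture
def fast_params():
    """Small population, short horizon — cheap kernel runs."""
    return ModelParams(n_labs=20, tournament_size=5, n_steps=2000, n_runs=2)
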