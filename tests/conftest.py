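import numpy as np
import pytest

from biocontinuum import (
    FitnessModel,
    Scenario,
    validate_distribution,
)

RPS_PAYOFF = [[0.0, -1.0, 1.0], [1.0, 0.0, -1.0], [-1.0, 1.0, 0.0]]


@pytest.fixture
def two_type_selection():
    """Constant selection f=[1,0] from the uniform start, target = fit vertex."""
    return Scenario(
        fitness=FitnessModel.constant([1.0, 0.0]),
        p0=validate_distribution([0.5, 0.5]),
        q=validate_distribution([1.0, 0.0]),
        t_span=(0.0, 10.0),
        n_points=501,
    )


@pytest.fixture
def rps_scenario():
    """Zero-sum rock-paper-scissors around the interior equilibrium."""
    return Scenario(
        fitness=FitnessModel.linear(RPS_PAYOFF),
        p0=validate_distribution([0.5, 0.3, 0.2]),
        q=validate_distribution([1 / 3, 1 / 3, 1 / 3]),
        t_span=(0.0, 50.0),
        n_points=2001,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230318)
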