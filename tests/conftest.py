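import numpy as np
import pytest

import hbfold


@pytest.fixture(scope="session")
def fx():
    """Published reference matrices and pattern table."""
    return hbfold.fixtures()


@pytest.fixture(scope="session")
def ala5_K(fx):
    return fx.ala5_rates


@pytest.fixture(scope="session")
def ala8_K(fx):
    return fx.ala8_rates


@pytest.fixture(scope="session")
def ala5_p(ala5_K):
    return hbfold.stationary_distribution(ala5_K)


@pytest.fixture(scope="session")
def ala8_p(ala8_K):
    return hbfold.stationary_distribution(ala8_K)


@pytest.fixture(scope="session")
def ala5_sim(ala5_K):
    """Three independent 5 μs CTMC trajectories at 1 ps framing."""
    return [
        hbfold.simulate_ctmc(
            hbfold.SimulationRecipe(
                rate_matrix=ala5_K, duration=5000.0, dt=0.001, seed=11 + s
            )
        )
        for s in range(3)
    ]


def symmetric_two_state(rate: float = 1.0) -> hbfold.RateMatrix:
    return hbfold.RateMatrix(K=np.array([[-rate, rate], [rate, -rate]]))
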