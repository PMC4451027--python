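import numpy as np
import pytest

from divlabsim import BenefitSpec, GameSpec, IBMConfig, TradeOff


@pytest.fixture(scope="session")
def weak_tradeoff():
    """The reference branching-enabled trade-off."""
    return TradeOff(k=0.25, alpha=0.15)


@pytest.fixture(scope="session")
def strong_tradeoff():
    return TradeOff(k=0.25, alpha=1.5)


@pytest.fixture(scope="session")
def gaussian_benefit():
    """Reference benefit: amplitude 30, sigma 5, mu 3.5 (peak between i=3 and 4)."""
    return BenefitSpec.gaussian()


@pytest.fixture(scope="session")
def game_I(weak_tradeoff, gaussian_benefit):
    return GameSpec(N=7, benefit=gaussian_benefit, sharing="I", trade_off=weak_tradeoff)


@pytest.fixture(scope="session")
def game_II(weak_tradeoff, gaussian_benefit):
    return GameSpec(N=7, benefit=gaussian_benefit, sharing="II", trade_off=weak_tradeoff)


@pytest.fixture(scope="session")
def game_I_strong(strong_tradeoff, gaussian_benefit):
    return GameSpec(N=7, benefit=gaussian_benefit, sharing="I", trade_off=strong_tradeoff)


@pytest.fixture(scope="session")
def tiny_game():
    """N=3 game with a tiny symmetric benefit table."""
    return GameSpec(N=3, benefit=BenefitSpec.from_table([1.0, 2.0, 2.0, 1.0]),
                    sharing="I", trade_off=TradeOff(k=0.25, alpha=0.5))


@pytest.fixture
def tiny_ibm_config():
    """A config small enough for per-test runs."""
    return IBMConfig.desk_scale(pop_size=60, groups_per_generation=60,
                                generations=200, seed=0, record_every=50)


def reference_beta(i, amplitude=30.0, sigma=5.0, mu=3.5):
    """Independent benefit evaluation used as an oracle in several tests."""
    import math

    return amplitude / (sigma * math.sqrt(2 * math.pi)) * math.exp(
        -((i - mu) ** 2) / (2 * sigma) ** 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240515)
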