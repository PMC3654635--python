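import pytest

from pgdhla.family import phase_trio
from pgdhla.panel import default_combinations, default_panel
from pgdhla.report import demo_family_reference, synthetic_demo_trio
from pgdhla.simulator import SimulationConfig, default_recomb_probs


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def combos():
    return default_combinations()


@pytest.fixture(scope="session")
def demo_trio(panel):
    return synthetic_demo_trio(panel)


@pytest.fixture(scope="session")
def family(panel):
    return demo_family_reference(panel)


@pytest.fixture
def zero_noise_config(panel, family):
    """Config with every stochastic rate zero (meiosis only, no crossovers)."""

    def make(n_embryos: int, seed: int = 0) -> SimulationConfig:
        return SimulationConfig(
            n_embryos=n_embryos,
            seed=seed,
            recomb_prob_by_interval=default_recomb_probs(
                family, panel, default=0.0, hotspot=0.0
            ),
        )

    return make
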