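import numpy as np
import pytest

from exomesieve import FilterConfig
from exomesieve.simulate import PlantedVariant, SimulationConfig, simulate_cohort
from exomesieve.model import Consequence


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20180507)


PANEL_GENES = tuple(f"PANEL{i:03d}" for i in range(40))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 6-patient cohort (1 sibling pair) with planted causal
    variants of every selectable class."""
    cfg = SimulationConfig(
        n_patients=6,
        n_families=1,
        variants_per_patient=200,
        seed=11,
        planted_causal=(
            PlantedVariant("OFFPANELX", Consequence.stop_gained),
            PlantedVariant(PANEL_GENES[0], Consequence.missense),
            PlantedVariant(PANEL_GENES[1], Consequence.inframe_indel),
            PlantedVariant(PANEL_GENES[2], Consequence.missense,
                           family_transmission=True),
        ),
    )
    return simulate_cohort(cfg, panel_genes=PANEL_GENES)
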