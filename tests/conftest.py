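import numpy as np
import pytest
from hypothesis import settings

from tempobal.config import bundled_config_path, load_config
from tempobal.demography import constant_size
from tempobal.simulate import BurnIn, SelectionModel, SimConfig, simulate_locus

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_cfg():
    return load_config(bundled_config_path("desk_scale"))


def small_sim_config(**overrides) -> SimConfig:
    """A fast selected configuration with the serial sampling design."""
    defaults = dict(
        locus_length=50_000.0,
        mu=1e-7,
        rho=1e-7,
        demography=constant_size(200, 25.0),
        selection=SelectionModel(s=0.3, onset_time=750.0),  # 30 generations
        sampling_scheme=((600.0, 10), (300.0, 10), (150.0, 10), (75.0, 10), (0.0, 40)),
        burn_in=BurnIn("coalescent"),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def selected_sample():
    """One simulated serial sample with a segregating focal variant."""
    return simulate_locus(small_sim_config(), seed=11)


@pytest.fixture(scope="session")
def neutral_sample():
    return simulate_locus(small_sim_config(selection=None), seed=12)
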