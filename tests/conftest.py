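import logging

import numpy as np
import pytest

from nirsflow.cohort import CohortConfig, VariabilityConfig, NoiseConfig
from nirsflow.forward import InstrumentConfig
from nirsflow.spectra import load_extinction_table

logging.getLogger("nirsflow").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def ext_table():
    return load_extinction_table()


def zero_variability():
    return VariabilityConfig(**{k: 0.0 for k in VariabilityConfig().model_dump()})


def zero_noise():
    return NoiseConfig(fdnirs_ln_amplitude=0.0, fdnirs_phase_rad=0.0, dcs_g2=0.0)


@pytest.fixture
def tiny_cohort_config():
    """5 subjects, all 7 sites, 2 repetitions: fast but structurally complete."""
    return CohortConfig(n_male=3, n_female=2, repetitions_per_site=2, seed=42)


@pytest.fixture
def clean_cohort_config():
    """Deterministic cohort: no biological variability, no instrument noise."""
    return CohortConfig(
        n_male=2, n_female=2, repetitions_per_site=1, seed=7,
        variability=zero_variability(), noise=zero_noise(),
    )
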