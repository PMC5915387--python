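import numpy as np
import pytest

from groovebend import (
    PAPER_ANGLE_PARAMS,
    BeamParameters,
    GeneratorConfig,
    generate_groove_records,
)

STUDY_LOAD_RATIO = 1.2e17  # fitted q/24EI, m^-3


@pytest.fixture(scope="session")
def angle_params():
    return PAPER_ANGLE_PARAMS


@pytest.fixture(scope="session")
def beam_params():
    return BeamParameters(q=0.03, EI=0.03 / (24 * STUDY_LOAD_RATIO))


@pytest.fixture(scope="session")
def noiseless_records():
    cfg = GeneratorConfig(
        seed=42, n_per_class=50, sigma_dL=0.0, sigma_angle_deg=0.0
    )
    return generate_groove_records(cfg)


@pytest.fixture(scope="session")
def noisy_records():
    cfg = GeneratorConfig(seed=42, n_per_class=50)
    return generate_groove_records(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
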