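import logging

import numpy as np
import pytest

from hipsnap import (
    AnatomicalParameters,
    PopulationConfig,
    build_anatomy,
    build_circumduction_sequence,
)

logging.getLogger("hipsnap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return PopulationConfig()


@pytest.fixture(scope="session")
def male_params():
    return AnatomicalParameters(
        neck_shaft_angle=125.0,
        anteversion=10.0,
        femoral_offset=44.0,
        ischiofemoral_distance=29.0,
        head_radius=25.0,
        sex="male",
    )


@pytest.fixture(scope="session")
def male_anatomy(male_params, default_config):
    return build_anatomy(male_params, default_config)


@pytest.fixture(scope="session")
def female_mean_anatomy(default_config):
    stats = default_config.statistics["female"]
    params = AnatomicalParameters(
        **{k: v[0] for k, v in stats.items()}, sex="female"
    )
    return build_anatomy(params, default_config)


@pytest.fixture(scope="session")
def risk_anatomy(default_config):
    """High-risk shape: anteversion +3 SD, offset -3 SD (female population)."""
    stats = default_config.statistics["female"]
    params = AnatomicalParameters(
        neck_shaft_angle=stats["neck_shaft_angle"][0],
        anteversion=stats["anteversion"][0] + 3 * stats["anteversion"][1],
        femoral_offset=stats["femoral_offset"][0] - 3 * stats["femoral_offset"][1],
        ischiofemoral_distance=stats["ischiofemoral_distance"][0],
        head_radius=stats["head_radius"][0],
        sex="female",
    )
    return build_anatomy(params, default_config)


@pytest.fixture(scope="session")
def short_motion():
    return build_circumduction_sequence(n_steps=20)


@pytest.fixture(scope="session")
def default_motion():
    return build_circumduction_sequence()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
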