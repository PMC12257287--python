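import numpy as np
import pytest

from dmdlitho import DmdSpec, LightSource, Objective, default_instrument


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture(scope="session")
def uv_source():
    return LightSource(
        max_power_mW=2.96,
        wavelength_um=0.395,
        dmd_slope_mW_per_unit_fraction=2.71,
        dmd_intercept_mW=-0.02,
    )


@pytest.fixture(scope="session")
def dmd():
    return DmdSpec(rows=600, cols=800)


@pytest.fixture
def objective_20x():
    return Objective(
        name="20x", magnification=20, na=0.75, measured_pixel_size_um=0.702
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
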