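import numpy as np
import pytest

from ecisfence.model import CellParams, ElectrodeSpec
from ecisfence.synth import GeneratorConfig


@pytest.fixture(scope="session")
def electrode_1e() -> ElectrodeSpec:
    return ElectrodeSpec.for_array("8W1E")


@pytest.fixture(scope="session")
def electrode_10e() -> ElectrodeSpec:
    return ElectrodeSpec.for_array("8W10E")


@pytest.fixture(scope="session")
def control_cells() -> CellParams:
    # the study's fitted control-layer morphology (assumed Cm of 1 uF/cm^2)
    return CellParams(rb=1.7267, cm=1.0, rc_um=11.72, h_nm=49.1535)


@pytest.fixture
def noiseless_config() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def noisy_config() -> GeneratorConfig:
    return GeneratorConfig(noise_sd=0.01, seed=0)


def ols_slope_two_pass(t: np.ndarray, y: np.ndarray) -> float:
    """Independent closed-form OLS slope (two-pass centering)."""
    tc = t - t.mean()
    yc = y - y.mean()
    return float(np.dot(tc, yc) / np.dot(tc, tc))
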