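import numpy as np
import pytest

from enose.io import DEFAULT_PHASE_BOUNDS
from enose.simulate import (
    SensorModel,
    default_sensor_models,
    simulate_calibration_series,
    simulate_curve,
)


@pytest.fixture
def noiseless_models_additive():
    """Full default array, additive O2 coupling, noise off."""
    return default_sensor_models(o2_mode="additive", noise_cv=0.0)


@pytest.fixture
def noiseless_models_multiplicative():
    return default_sensor_models(o2_mode="multiplicative", noise_cv=0.0)


@pytest.fixture
def single_model():
    """One cheap channel for fine-grained curve tests."""
    return SensorModel(
        "TGS2603_a", r0=40_000.0, beta_o2=0.9, alpha_vc=0.45,
        tau_on=18.0, tau_off=55.0, noise_cv=0.0, o2_mode="additive",
    )


@pytest.fixture
def calibration_noiseless_additive(noiseless_models_additive):
    return simulate_calibration_series(
        noiseless_models_additive, rate_hz=0.25, seed=11
    )


@pytest.fixture
def calibration_noiseless_multiplicative(noiseless_models_multiplicative):
    return simulate_calibration_series(
        noiseless_models_multiplicative, rate_hz=0.25, seed=11
    )


@pytest.fixture
def measurement(noiseless_models_multiplicative):
    """A valid 8-channel measurement at 1 Hz (961 samples per channel)."""
    from enose.io import ENoseMeasurement

    curves = {
        cid: simulate_curve(m, 0.5, 0.30, DEFAULT_PHASE_BOUNDS, rate_hz=1.0)
        for cid, m in noiseless_models_multiplicative.items()
    }
    return ENoseMeasurement(
        animal_id="pig01", group="LPS", timepoint="t60", fio2=0.30, curves=curves
    )
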