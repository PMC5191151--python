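import pytest

from posturekit import SensorSpec, build_atan_lut


@pytest.fixture(scope="session")
def lut16():
    return build_atan_lut(16)


@pytest.fixture
def quiet_spec():
    """Noiseless sensor: quantisation is the only distortion."""
    return SensorSpec(noise_sd_g=0.0)


@pytest.fixture
def default_spec():
    return SensorSpec()
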