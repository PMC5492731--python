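import numpy as np
import pytest

from henmon.frame_io import TemperatureCalibration, ThermalFrame


@pytest.fixture
def cal() -> TemperatureCalibration:
    """Default linear calibration: 0 degC at level 0, 0.1 degC per level."""
    return TemperatureCalibration()


@pytest.fixture
def make_frame(cal):
    """Build a ThermalFrame from a raw integer grid with the default calibration."""

    def _make(pixels, **kwargs) -> ThermalFrame:
        return ThermalFrame(pixels=np.asarray(pixels, dtype=np.uint8),
                            calibration=cal, **kwargs)

    return _make
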