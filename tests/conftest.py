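import numpy as np
import pytest

from bapscal import CalibrationDataset, CalibrationProtocol


@pytest.fixture
def protocol() -> CalibrationProtocol:
    """Standard 8-exchange calibration protocol in a 1 L chamber."""
    return CalibrationProtocol()


@pytest.fixture
def exact_line_dataset() -> CalibrationDataset:
    """Three points lying exactly on y = 1 + 2x."""
    return CalibrationDataset.from_arrays(
        [[0.0], [1.0], [2.0]], [1.0, 3.0, 5.0], sensor_kind="pressure"
    )


@pytest.fixture
def noisy_pressure_dataset() -> CalibrationDataset:
    """Nine-point pressure calibration with known truth y = 700 + 250 x."""
    rng = np.random.default_rng(42)
    x = np.linspace(0.4, 2.0, 9)
    y = 700.0 + 250.0 * x + rng.normal(0.0, 0.4, size=9)
    return CalibrationDataset.from_arrays(x[:, None], y, sensor_kind="pressure")
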