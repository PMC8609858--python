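import pytest

from chlorosig import CalibrationMeasurement, OpticalParams
from chlorosig.units import cells_per_ml_to_per_m3


@pytest.fixture
def params() -> OpticalParams:
    """Default optical parameters: r = 3 μm, Kd = 0.57/m, u = 9.07e-12."""
    return OpticalParams()


@pytest.fixture
def reference_measurement() -> CalibrationMeasurement:
    """The bulk laboratory measurement anchoring the per-cell flux."""
    return CalibrationMeasurement(
        measured_cfpfd=2.418e-2,
        cell_density_n=cells_per_ml_to_per_m3(1.6e6),
        sample_volume=1e-6,
        geometry_factor=6.0,
    )
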