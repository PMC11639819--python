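import warnings

import pytest
from hypothesis import HealthCheck, settings

from pedibca.estimation import PhysiologicalRangeWarning
from pedibca.sensor_models import fit_load_cell_calibration

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def bench_calibration():
    """Two-point calibration from the bench procedure: zero load at
    100000 counts, a 30 kg reference at 400000 counts."""
    return fit_load_cell_calibration(100_000.0, 30.0, 400_000.0)


@pytest.fixture(autouse=True)
def _quiet_soft_range_warnings():
    """Soft physiological-range flags are expected on synthetic cohorts."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PhysiologicalRangeWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
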