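import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from thermoclot.assay_units import ConditionProfile
from thermoclot.inactivation_kinetics import ThermalSeries

# Published activity-vs-temperature row for the free enzyme (SU/ml at
# 25..60 degC in 5 degC steps); plateau at 35/40 degC, optimum 35 degC.
FREE_TEMPERATURE_ACTIVITIES = (400, 1200, 2400, 2400, 2000, 1750, 1200, 800)
TEMPERATURES_C = (25, 30, 35, 40, 45, 50, 55, 60)


@pytest.fixture
def free_temperature_profile() -> ConditionProfile:
    return ConditionProfile.from_pairs(
        list(zip(TEMPERATURES_C, FREE_TEMPERATURE_ACTIVITIES)),
        variable="temperature_C", form="free")


@pytest.fixture
def noiseless_series() -> ThermalSeries:
    """Exact first-order decay with kd = 0.01 min^-1."""
    times = (0.0, 15.0, 30.0, 45.0, 60.0)
    kd = 0.01
    return ThermalSeries(
        level=55.0,
        times_min=times,
        residual_activity=tuple(100.0 * np.exp(-kd * t) for t in times),
        form="free")


def ols_normal_equations(x, y):
    """Independent least-squares oracle: slope and intercept straight from
    the normal equations, no library fitting routine."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
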