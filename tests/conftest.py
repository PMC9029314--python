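import numpy as np
import pytest

from albind import GroundTruth, TitrationPoint, TitrationSeries


@pytest.fixture
def noiseless_truth() -> GroundTruth:
    return GroundTruth(noise_sd=0.0, seed=123)


@pytest.fixture
def simple_series() -> TitrationSeries:
    """Exact Stern-Volmer data, Ksv = 1e4 M^-1, F0 = 1000."""
    conc = np.array([0, 5, 10, 15, 20, 25, 30, 35]) * 1e-6
    f = 1000.0 / (1.0 + 1e4 * conc)
    return TitrationSeries(
        tuple(TitrationPoint(float(c), float(v)) for c, v in zip(conc, f)),
        temperature_K=295.0,
    )


def ols_slope_intercept(x, y):
    """Closed-form OLS oracle, independent of the fitting path under test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xb, yb = x.mean(), y.mean()
    slope = ((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum()
    return slope, yb - slope * xb
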