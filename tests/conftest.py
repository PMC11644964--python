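import numpy as np
import pandas as pd
import pytest

import gluforecast as gf


@pytest.fixture(scope="session")
def table1():
    return gf.table1_fixture()


@pytest.fixture(scope="session")
def sine_series():
    """Noiseless sine, 500 points at 15-minute spacing: a fully learnable
    univariate forecasting task."""
    t = np.arange(500)
    values = 7.0 + 3.0 * np.sin(2.0 * np.pi * t / 40.0)
    ts = pd.date_range("2021-01-01", periods=500, freq="15min").values
    return gf.GlucoseSeries(ts, values)


@pytest.fixture(scope="session")
def ar1_series():
    """Pure AR(1) glucose trace (phi=0.5) where the persistence baseline is
    provably ~15% above the optimal one-step RMSE."""
    params = gf.CgmSimParams(
        n_points=600, circadian_amplitude=0.0, meal_times=(),
        noise_sd=0.3, ar_coefficient=0.5, seed=7,
    )
    return gf.generate_cgm(params)


@pytest.fixture(scope="session")
def cgm_series():
    """Full-featured synthetic CGM trace (circadian + meals + AR noise)."""
    return gf.generate_cgm(gf.CgmSimParams(n_points=1000, seed=11))
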