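import numpy as np
import pandas as pd
import pytest

from fluxdrought import FluxTimeSeries


@pytest.fixture
def daily_series():
    """Three years of complete, well-behaved daily data."""
    idx = pd.date_range("2015-01-01", "2017-12-31", freq="D")
    rng = np.random.default_rng(42)
    gpp = 3.0 + rng.uniform(-1, 1, len(idx))
    er = 1.5 + rng.uniform(-0.5, 0.5, len(idx))
    data = pd.DataFrame({
        "GPP": gpp, "ER": er, "NEP": gpp - er,
        "ET": 2.0 + rng.uniform(-0.5, 0.5, len(idx)),
        "P": rng.exponential(2.0, len(idx)),
        "VPD": 1.0 + rng.uniform(-0.3, 0.3, len(idx)),
        "Ta": 20.0 + rng.uniform(-5, 5, len(idx)),
        "RH": 60.0 + rng.uniform(-10, 10, len(idx)),
        "u": 2.0 + rng.uniform(-0.5, 0.5, len(idx)),
        "Rn": 12.0 + rng.uniform(-3, 3, len(idx)),
    }, index=idx)
    return FluxTimeSeries("testsite", "daily", data)


@pytest.fixture
def monthly_water_table():
    """Five years of monthly P/PET with a seasonal cycle, as a DataFrame."""
    idx = pd.date_range("2014-01-01", periods=60, freq="MS")
    month = idx.month.to_numpy()
    P = 60.0 + 40.0 * np.cos(2 * np.pi * (month - 1) / 12)
    PET = 120.0 + 30.0 * np.cos(2 * np.pi * (month - 1) / 12)
    return pd.DataFrame({"P": P, "PET": PET}, index=idx)
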