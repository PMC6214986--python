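import numpy as np
import pandas as pd
import pytest

from riacd import HourlySeries, ModelOrder, SACDParams, simulate_acd


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def acd111_params():
    """Well-behaved ACD(1,1) parameters with unit stationary mean."""
    return SACDParams(omega=0.1, alpha=[0.1], beta=[0.8])


@pytest.fixture(scope="session")
def acd_sample():
    """One simulated ACD(1,1) path shared across tests (N=2000)."""
    params = SACDParams(omega=0.1, alpha=[0.1], beta=[0.8])
    d, psi = simulate_acd(params, ModelOrder(1, 1, 0), n=2000, seed=12345)
    return params, d, psi


def make_hourly(values, start="2013-01-01", station="1", pollutant="PM2.5"):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return HourlySeries(station, pollutant, pd.Series(values, index=idx, dtype=float))


@pytest.fixture
def hourly_csv(tmp_path):
    """Factory writing a standard hourly CSV from row tuples."""

    def _write(rows, name="input.csv"):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=["station", "pollutant", "timestamp", "value"])
        df.to_csv(path, index=False)
        return path

    return _write


def fractional_gaussian_noise(h_exp, n, rng):
    """Exact fGn by circulant embedding (test oracle for the DFA estimator)."""
    k = np.arange(n + 1, dtype=float)
    g = 0.5 * ((k + 1) ** (2 * h_exp) - 2 * k ** (2 * h_exp) + np.abs(k - 1) ** (2 * h_exp))
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam[lam < 0] = 0.0
    m = len(row)
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(np.sqrt(lam / (2 * m)) * w)
    return f.real[:n]
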