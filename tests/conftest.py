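import numpy as np
import pytest

from rapkit import synth
from rapkit.arima import ArimaSpec
from rapkit.core import IndexSeries


@pytest.fixture(scope="session")
def short_recording():
    """10-min pulsatile recording with moderate coupling."""
    params = synth.WaveformParams(duration=600.0, coupling=0.5, seed=7)
    return synth.simulate_pulsatile(params)


@pytest.fixture(scope="session")
def coupled_recording():
    """One-hour recording with strong coupling (high-RAP regime)."""
    params = synth.WaveformParams(duration=3600.0, coupling=0.9, seed=11)
    return synth.simulate_pulsatile(params)


@pytest.fixture
def minute_series():
    """Minute-level AR(1)-on-differences series (ARIMA(1,1,1) generator)."""
    return synth.simulate_arma(
        ArimaSpec(1, 1, 1), ar_coeffs=[0.7], ma_coeffs=[0.3], n=800,
        innovation_sd=0.2, seed=3, resolution="1min", name="RAP",
    )


def make_series(values, resolution="1min", name="x", t0=None):
    values = np.asarray(values, dtype=float)
    step = {"10s": 10.0, "1min": 60.0, "10min": 600.0}[resolution]
    start = step if t0 is None else t0
    time = start + step * np.arange(values.size)
    return IndexSeries(name=name, time=time, values=values, resolution=resolution)
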