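import numpy as np
import pytest

from nirsosc import (
    OscillationSpec,
    PathlengthModel,
    generate_concentration_series,
    synthetic_extinction_table,
)

DRIFT = {c: (0.0, 2.0, -3.0, 1.5) for c in ("oxCCO", "HbO2", "HHb")}


@pytest.fixture(scope="session")
def clean_series():
    """Noiseless, jitter-free, drift-free 1/480 Hz oscillation, 1 h at 1 Hz."""
    spec = OscillationSpec(noise_sd=0.0, period_jitter_sd=0.0)
    return generate_concentration_series(spec).with_composites()


@pytest.fixture(scope="session")
def noisy_series():
    """Realistic single recording: jitter, drift and measurement noise."""
    spec = OscillationSpec(
        period_jitter_sd=0.02, noise_sd=0.05, drift_coefficients=DRIFT, seed=7
    )
    return generate_concentration_series(spec).with_composites()


@pytest.fixture(scope="session")
def extinction_table():
    return synthetic_extinction_table()


@pytest.fixture(scope="session")
def unit_pathlength():
    return PathlengthModel(geometric_distance=1.0, dpf=1.0)


def make_sinusoid_series(lags: dict[str, float], f: float = 1.0 / 480.0, n: int = 3600):
    """Pure sinusoid channels with the given phase lags (radians vs oxCCO)."""
    t = np.arange(n, dtype=float)
    from nirsosc import ChromophoreTimeSeries

    channels = {name: np.sin(2 * np.pi * f * t + lag) for name, lag in lags.items()}
    return ChromophoreTimeSeries(t, channels)
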