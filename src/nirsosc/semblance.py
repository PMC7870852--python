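"""Complex-Morlet wavelet transform and phase semblance.

Semblance resolves the phase relationship between two signals in both time
and frequency: with ``W_a(t, f)`` and ``W_b(t, f)`` the complex continuous
wavelet transforms, the cross-wavelet field is ``C = W_a · conj(W_b)`` and

    semblance(t, f) = cos(arg C) = Re(C) / |C|  ∈ [−1, +1]

so +1 means the signals are locally in phase, 0 in quadrature (90°), and −1
antiphase.  Averaged over time at the animal's dominant slow-wave frequency
it yields one phase-coupling number per signal pair.

The CWT uses the complex Morlet mother wavelet
``psi(u) = pi^{-1/4} exp(i*w0*u) exp(-u^2/2)`` evaluated in the frequency
domain (Torrence & Compo 1998): at scale ``s`` the daughter's transform is
``sqrt(2*pi*s/dt) * pi^{-1/4} * H(w) * exp(-(s*w - w0)^2 / 2)``, and scales
map to Fourier frequencies by ``f = (w0 + sqrt(2 + w0^2)) / (4*pi*s)``.  The
centre-frequency parameter ``w0`` defaults to 6, the standard
time/frequency-resolution compromise at which the wavelet is admissible in
practice.

At millihertz frequencies the cone of influence (COI; the edge-affected
region, e-folding time sqrt(2)·s) covers much of a one-hour record, so
summaries are reported both with edge cells included (the default, matching
full-record averaging) and COI-masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataFormatError
from .timeseries import ChromophoreTimeSeries

#: haemoglobin channels paired against oxCCO in the per-animal panel
PANEL_PAIRS = ("HHb", "HbO2", "HbT", "HbDiff")

#: cross-power below this fraction of the field maximum has no defined phase
_POWER_FLOOR = 1e-12


@dataclass
class WaveletConfig:
    """Complex-Morlet CWT settings.

    ``frequencies`` defaults to 64 log-spaced voices over 0.0005–0.01 Hz,
    bracketing the slow-wave band with margin on both sides.
    """

    center_frequency_parameter: float = 6.0
    frequencies: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.0005, 0.01, 64)
    )
    coi_handling: str = "include"  # or "mask"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.center_frequency_parameter < 5:
            raise ConfigurationError(
                "center_frequency_parameter must be >= 5 for practical admissibility"
            )
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ConfigurationError("frequency grid must be positive and increasing")
        if self.coi_handling not in ("include", "mask"):
            raise ConfigurationError("coi_handling must be 'include' or 'mask'")

    def scales(self, dt: float) -> np.ndarray:
        """Wavelet scales (s) whose Fourier-equivalent frequency matches the grid."""
        w0 = self.center_frequency_parameter
        fourier_factor = (4.0 * np.pi) / (w0 + np.sqrt(2.0 + w0**2))
        return 1.0 / (fourier_factor * self.frequencies)


@dataclass
class SemblanceMap:
    """Time × frequency semblance field with cross power and COI flags."""

    time: np.ndarray  # s
    frequency: np.ndarray  # Hz
    semblance: np.ndarray  # (n_freq, n_time), NaN where phase undefined
    cross_power: np.ndarray  # (n_freq, n_time), |C|
    coi_mask: np.ndarray  # (n_freq, n_time) bool, True = edge-affected
    pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        finite = self.semblance[np.isfinite(self.semblance)]
        # tolerance only for float roundoff; semblance is a cosine by construction
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise DataFormatError("semblance values outside [-1, 1]")


@dataclass
class SemblanceSummary:
    """Time-averaged semblance for one signal pair at one frequency."""

    pair: tuple[str, str]
    at_frequency: float  # Hz, the grid frequency actually used
    mean_semblance: float
    mean_semblance_coi_masked: float
    band_halfwidth_seconds: float = 50.0  # display band: period ± 50 s


def morlet_cwt(
    series: ChromophoreTimeSeries,
    channel: str,
    config: WaveletConfig | None = None,
) -> np.ndarray:
    """Complex Morlet CWT of one channel.

    Returns the (n_freq, n_time) complex coefficient field on the config's
    frequency grid.  The signal is mean-removed and zero-padded to the next
    power of two before the FFT-domain convolution; padding is stripped from
    the output.  The modulus of a sinusoidal input peaks at the voice nearest
    the sinusoid's frequency.
    """
    if config is None:
        config = WaveletConfig()
    nyquist = series.sampling_rate / 2.0
    if np.any(config.frequencies >= nyquist):
        raise ConfigurationError(
            f"wavelet frequencies must be below Nyquist ({nyquist} Hz)"
        )
    x = series[channel] - series[channel].mean()
    n = x.size
    dt = series.dt
    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)

    w0 = config.center_frequency_parameter
    scales = config.scales(dt)
    norm = np.pi ** (-0.25) * np.sqrt(2.0 * np.pi * scales / dt)  # per-scale energy norm
    # analytic wavelet: support only on positive frequencies
    arg = scales[:, None] * omega[None, :] - w0
    daughters = norm[:, None] * np.exp(-0.5 * arg**2) * (omega[None, :] > 0)
    coeffs = np.fft.ifft(xhat[None, :] * daughters, axis=1)[:, :n]
    return coeffs


def coi_mask(n_samples: int, dt: float, config: WaveletConfig) -> np.ndarray:
    """Boolean (n_freq, n_time) field, True where edge effects reach.

    The Morlet e-folding time is sqrt(2)·s: a cell closer than that to either
    record edge is flagged as inside the cone of influence.
    """
    t = np.arange(n_samples) * dt
    edge_distance = np.minimum(t, t[-1] - t)
    efold = np.sqrt(2.0) * config.scales(dt)
    return edge_distance[None, :] < efold[:, None]


def semblance_map(
    series: ChromophoreTimeSeries,
    channel_a: str,
    channel_b: str,
    config: WaveletConfig | None = None,
) -> SemblanceMap:
    """Cross-wavelet semblance between two channels of one recording.

    Cells whose cross power falls below 1e-12 × the field maximum carry no
    phase information and are set to NaN rather than reporting noise-driven
    ±1 values.
    """
    if config is None:
        config = WaveletConfig()
    wa = morlet_cwt(series, channel_a, config)
    wb = morlet_cwt(series, channel_b, config)
    cross = wa * np.conj(wb)
    power = np.abs(cross)
    valid = power > _POWER_FLOOR * power.max() if power.max() > 0 else np.zeros_like(power, bool)
    semb = np.full(power.shape, np.nan)
    np.divide(cross.real, power, out=semb, where=valid)
    np.clip(semb, -1.0, 1.0, out=semb)
    return SemblanceMap(
        time=series.time.copy(),
        frequency=config.frequencies.copy(),
        semblance=semb,
        cross_power=power,
        coi_mask=coi_mask(series.n_samples, series.dt, config),
        pair=(channel_a, channel_b),
    )


def mean_semblance(smap: SemblanceMap, at_frequency: float) -> SemblanceSummary:
    """Time-average of the semblance row nearest ``at_frequency``.

    Averages over the full record by default (edge cells included); the
    COI-masked mean over interior cells is always reported alongside.
    """
    f = smap.frequency
    if not f[0] <= at_frequency <= f[-1]:
        raise ConfigurationError(
            f"frequency {at_frequency} Hz outside wavelet grid [{f[0]}, {f[-1]}] Hz"
        )
    row = int(np.argmin(np.abs(f - at_frequency)))
    values = smap.semblance[row]
    if not np.isfinite(values).any():
        raise DataFormatError("no defined semblance cells at the requested frequency")
    full = float(np.nanmean(values))
    interior = values[~smap.coi_mask[row]]
    masked = float(np.nanmean(interior)) if np.isfinite(interior).any() else float("nan")
    return SemblanceSummary(smap.pair, float(f[row]), full, masked)


def animal_semblance_panel(
    series: ChromophoreTimeSeries,
    dominant_frequency: float,
    config: WaveletConfig | None = None,
) -> dict[str, SemblanceSummary]:
    """Semblance of each haemoglobin signal against oxCCO at one frequency.

    ``dominant_frequency`` is the animal's slow-wave frequency from the FFT
    stage.  Returns one summary per pair (HHb, HbO2, HbT, HbDiff — each vs
    oxCCO), carrying the period ± 50 s display band used for map renderings.
    """
    if config is None:
        config = WaveletConfig()
    series.require("oxCCO", *PANEL_PAIRS)
    out: dict[str, SemblanceSummary] = {}
    for hb in PANEL_PAIRS:
        smap = semblance_map(series, hb, "oxCCO", config)
        out[hb] = mean_semblance(smap, dominant_frequency)
    return out
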