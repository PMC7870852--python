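"""Synthetic cohorts of retinal slow-wave chromophore oscillations.

No recordings accompany the study this package operationalises, so every
downstream stage is exercised against generated series with *known* ground
truth.  The generator emulates the reported phenomenology:

* a common slow-wave oscillator at 0.001–0.002 Hz (periods of minutes) that
  all chromophore channels ride with fixed inter-channel phase lags — deoxy
  haemoglobin locked to the mitochondrial oxCCO signal, the haemoglobin
  difference near antiphase;
* cycle-to-cycle period irregularity, modelled as a phase random walk whose
  fractional step s.d. is the ``period_jitter_sd`` parameter (this smoothly
  broadens the spectral peak, the way ageing/knockout cohorts present);
* slow instrumental drift as a polynomial (order ≤ 6, hence exactly
  removable by the pipeline's detrend) in normalised time;
* additive i.i.d. Gaussian measurement noise.

Cohort presets encode the four experimental groups (young/old C57 wild-type
and young/old CFH⁻/⁻ knockout mice): period 8 min in young controls
lengthening to 14–16 min, with regularity degrading in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError
from .timeseries import CHROMOPHORE_CHANNELS, ChromophoreTimeSeries
from .unmixing import AttenuationSeries, ExtinctionTable, PathlengthModel, design_matrix

COHORT_NAMES = ("young_C57", "old_C57", "young_CFH", "old_CFH")


@dataclass
class OscillationSpec:
    """Ground-truth parameters for one synthetic animal recording.

    Parameters
    ----------
    base_frequency
        Slow-wave frequency in Hz (nominally 0.001–0.002).
    amplitude_per_channel
        Oscillation amplitude per channel, µM.  oxCCO runs an order of
        magnitude below haemoglobin, as in tissue.
    phase_lag_per_channel
        Phase of each channel relative to oxCCO, radians (oxCCO itself is 0).
    period_jitter_sd
        Fractional s.d. of the per-sample phase increment; 0 = perfectly
        periodic.
    drift_coefficients
        Per-channel polynomial coefficients (lowest order first, length ≤ 7)
        evaluated on normalised time t ∈ [0, 1], µM.
    noise_sd
        Additive white-noise s.d., µM (same for every channel).
    duration, sampling_rate
        Record length (s) and rate (Hz); their product must be an integer
        sample count ≥ 2.
    seed
        Master seed; channel noise streams are spawned from it.
    """

    base_frequency: float = 1.0 / 480.0
    amplitude_per_channel: Mapping[str, float] = field(
        default_factory=lambda: {"oxCCO": 0.15, "HbO2": 0.8, "HHb": 1.0}
    )
    phase_lag_per_channel: Mapping[str, float] = field(
        default_factory=lambda: {"oxCCO": 0.0, "HbO2": 0.0, "HHb": 0.0}
    )
    period_jitter_sd: float = 0.0
    drift_coefficients: Mapping[str, tuple] = field(default_factory=dict)
    noise_sd: float = 0.0
    duration: float = 3600.0
    sampling_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_frequency <= 0:
            raise ConfigurationError("base_frequency must be positive")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling_rate must be positive")
        if self.sampling_rate <= 2 * self.base_frequency:
            raise ConfigurationError("sampling_rate must exceed twice base_frequency")
        if self.period_jitter_sd < 0:
            raise ConfigurationError("period_jitter_sd must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ConfigurationError(
                "duration x sampling_rate must be an integer sample count >= 2"
            )
        for ch, coeffs in self.drift_coefficients.items():
            if len(coeffs) > 7:
                raise ConfigurationError(
                    f"drift polynomial for {ch!r} exceeds order 6 ({len(coeffs) - 1})"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def period_seconds(self) -> float:
        return 1.0 / self.base_frequency


@dataclass
class CohortPreset:
    """A named experimental group with its generator parameters."""

    name: str
    spec: OscillationSpec


# period (s), jitter, HbO2 lag, HHb lag — young controls tight at 8 min with
# both haemoglobins phase-locked to oxCCO; aged/knockout groups slower, less
# regular, with a growing oxygenated-blood phase lag.  HHb amplitude exceeds
# HbO2 so the derived HbDiff = HbO2 - HHb sits near antiphase to oxCCO.
_PRESETS: dict[str, dict] = {
    "young_C57": dict(period=480.0, jitter=0.02, lag_hbo2=0.0, lag_hhb=0.0),
    "old_C57": dict(period=840.0, jitter=0.12, lag_hbo2=-0.9, lag_hhb=-0.2),
    "young_CFH": dict(period=960.0, jitter=0.16, lag_hbo2=-0.6, lag_hhb=-0.2),
    "old_CFH": dict(period=960.0, jitter=0.20, lag_hbo2=-1.1, lag_hhb=-0.3),
}

#: modest slow drift over the hour, µM; identical shape every channel rides
_DEFAULT_DRIFT = (0.0, 2.0, -3.0, 1.5)


def cohort_preset(name: str, *, seed: int = 0, noise_sd: float = 0.05) -> CohortPreset:
    """Fully populated :class:`OscillationSpec` for one of the four groups.

    ``young_C57`` → 480 s period; ``old_C57`` → 840 s; both CFH⁻/⁻ groups →
    960 s; period jitter increases young_C57 < old_C57 < young_CFH < old_CFH.
    """
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown cohort {name!r}; choose one of {COHORT_NAMES}"
        )
    p = _PRESETS[name]
    spec = OscillationSpec(
        base_frequency=1.0 / p["period"],
        amplitude_per_channel={"oxCCO": 0.15, "HbO2": 0.8, "HHb": 1.0},
        phase_lag_per_channel={"oxCCO": 0.0, "HbO2": p["lag_hbo2"], "HHb": p["lag_hhb"]},
        period_jitter_sd=p["jitter"],
        drift_coefficients={ch: _DEFAULT_DRIFT for ch in CHROMOPHORE_CHANNELS},
        noise_sd=noise_sd,
        duration=3600.0,
        sampling_rate=1.0,
        seed=seed,
    )
    return CohortPreset(name, spec)


def generate_concentration_series(spec: OscillationSpec) -> ChromophoreTimeSeries:
    """Generate oxCCO / HbO2 / HHb series from one spec.

    The instantaneous phase is a random walk,
    ``phi[n+1] = phi[n] + 2*pi*f*dt * (1 + eta[n])`` with
    ``eta ~ N(0, period_jitter_sd)``, shared across channels so inter-channel
    lags stay exact even under jitter.  Each channel is
    ``A_c * sin(phi + lag_c) + drift_c(t/T) + noise``.  Deterministic for a
    given spec and seed; ground truth is echoed in the metadata.
    """
    n = spec.n_samples
    dt = 1.0 / spec.sampling_rate
    time = np.arange(n) * dt
    t_norm = time / (time[-1] if time[-1] > 0 else 1.0)

    # one stream for the shared phase walk, one per channel for noise
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(1 + len(CHROMOPHORE_CHANNELS))
    phase_rng = np.random.default_rng(streams[0])

    base_step = 2.0 * np.pi * spec.base_frequency * dt
    if spec.period_jitter_sd > 0:
        # per-sample step noise scaled by sqrt(samples per cycle) so that the
        # *accumulated* phase error over one cycle has fractional s.d. equal
        # to period_jitter_sd — i.e. the parameter really is the
        # cycle-to-cycle period jitter, not a per-sample quantity
        samples_per_cycle = spec.sampling_rate / spec.base_frequency
        step_sd = spec.period_jitter_sd * np.sqrt(samples_per_cycle)
        steps = base_step * (1.0 + step_sd * phase_rng.standard_normal(n - 1))
    else:
        steps = np.full(n - 1, base_step)
    phase = np.concatenate(([0.0], np.cumsum(steps)))
    if spec.period_jitter_sd == 0:
        phase = 2.0 * np.pi * spec.base_frequency * time  # exact closed form

    channels: dict[str, np.ndarray] = {}
    for k, name in enumerate(CHROMOPHORE_CHANNELS):
        amp = float(spec.amplitude_per_channel.get(name, 0.0))
        lag = float(spec.phase_lag_per_channel.get(name, 0.0))
        x = amp * np.sin(phase + lag)
        coeffs = spec.drift_coefficients.get(name)
        if coeffs:
            x = x + np.polynomial.polynomial.polyval(t_norm, np.asarray(coeffs, dtype=float))
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng(streams[1 + k])
            x = x + spec.noise_sd * noise_rng.standard_normal(n)
        channels[name] = x

    meta = {
        "synthetic": {
            "base_frequency_hz": spec.base_frequency,
            "period_s": spec.period_seconds,
            "period_jitter_sd": spec.period_jitter_sd,
            "noise_sd": spec.noise_sd,
            "amplitude_per_channel": dict(spec.amplitude_per_channel),
            "phase_lag_per_channel": dict(spec.phase_lag_per_channel),
            "seed": spec.seed,
        }
    }
    return ChromophoreTimeSeries(time, channels, meta)


def generate_attenuation_series(
    conc: ChromophoreTimeSeries,
    table: ExtinctionTable,
    pathlength: PathlengthModel,
    noise_sd: float = 0.0,
    *,
    seed: int | None = None,
) -> AttenuationSeries:
    """Forward modified Beer–Lambert model: concentrations → ΔA spectra.

    ``dA(lambda, t) = d*DPF(lambda) * sum_c eps_c(lambda) * dc_c(t) * 1e-3``
    plus optional white noise (OD units).  Channel names must match the
    extinction table's chromophores exactly.
    """
    missing = [c for c in table.chromophore_names if c not in conc.channels]
    if missing:
        from .exceptions import ChannelError

        raise ChannelError(
            f"concentration series lacks chromophore channel(s) {missing}; "
            f"extinction table expects {list(table.chromophore_names)}"
        )
    design = design_matrix(table, pathlength)  # (n_wl, n_c)
    conc_matrix = np.stack([conc[c] for c in table.chromophore_names])  # (n_c, n_t)
    values = (design @ conc_matrix).T  # (n_t, n_wl)
    if noise_sd > 0:
        rng = np.random.default_rng(conc.metadata.get("synthetic", {}).get("seed", 0) if seed is None else seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return AttenuationSeries(conc.time.copy(), table.wavelengths.copy(), values)


def synthetic_extinction_table(
    n_wavelengths: int = 120,
    wavelength_range: tuple[float, float] = (780.0, 900.0),
) -> ExtinctionTable:
    """A smooth synthetic stand-in for a published extinction compilation.

    The study cites an external extinction table that is not printed, so
    tests and examples use this surrogate: three smooth, linearly
    independent NIR spectra with haemoglobin-like magnitudes (mM⁻¹ cm⁻¹) and
    a broad oxCCO-like band.  Synthetic — not a literature compilation.
    """
    wl = np.linspace(*wavelength_range, n_wavelengths)
    u = (wl - wl[0]) / (wl[-1] - wl[0])  # 0..1
    hbo2 = 1.0 + 2.2 * u + 1.1 * np.exp(-((wl - 850.0) / 35.0) ** 2)
    hhb = 2.5 - 1.5 * u + 1.8 * np.exp(-((wl - 760.0) / 30.0) ** 2)
    oxcco = 2.0 * np.exp(-((wl - 830.0) / 45.0) ** 2) + 0.3
    return ExtinctionTable(wl, np.column_stack([hbo2, hhb, oxcco]), ("HbO2", "HHb", "oxCCO"))
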