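# Methods

This note documents the models implemented in `nirsosc`, the choices made
where the underlying method descriptions were open, and what the synthetic
tests do and do not establish.

## Spectral unmixing (modified Beer–Lambert / UCLn)

Differential attenuation at wavelength λ and time t is modelled as

    ΔA(λ, t) = d · DPF(λ) · Σ_c ε_c(λ) · Δc_c(t) · 10⁻³

with ΔA in base-10 optical density, ε in mM⁻¹cm⁻¹, Δc in µM, d the
source–detector distance in cm and DPF the dimensionless differential
pathlength factor.  Per time point the three chromophores (HbO₂, HHb,
oxCCO) are recovered by ordinary least squares over all wavelengths,
solved via SVD (`numpy.linalg.lstsq`) rather than normal equations — with
>100 wavelength rows this is the numerically stable route.  Designs with a
condition number above 10⁸ are rejected with an explicit error.

Choices:

- **Extinction table is an input, not a constant.**  The published
  compilations differ and none is canonical for this instrument class; the
  loader accepts delimited text with a `# log_base: 10|e` header and
  converts natural-log tables by 1/ln 10.  A smooth synthetic surrogate
  table (clearly labelled synthetic) is provided for tests and examples.
- **DPF defaults to 1 with a logged warning.**  No mouse-eye DPF is
  established, so absolute µM values are conventional; every downstream
  metric (period, regularity, semblance) is invariant to this overall scale.
- **Wavelength matching is exact** after rounding to 0.01 nm; no
  interpolation of extinction spectra is performed.
- Composite channels are always derived (`HbT = HHb + HbO₂`,
  `HbDiff = HbO₂ − HHb`), never generated or stored independently, so the
  defining identities hold to machine precision by construction.

## Slow-wave isolation

- **Low-pass**: order-5 Butterworth at 0.01 Hz applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase.  Zero phase is mandatory, not cosmetic:
  all downstream results are phase analyses and a causal filter's group
  delay (tens of seconds at these frequencies) would bias every semblance.
- **Detrend**: least-squares polynomial of order 6 (default) per channel,
  fitted on time scaled to [−1, 1] for conditioning.  Any drift that is
  itself a polynomial of degree ≤ 6 is removed exactly; the subtracted trend
  is returnable for inspection.
- Default order is filter → detrend; the reverse is available by config and
  the order used is recorded in the output metadata.
- Non-finite samples are rejected outright; no imputation.

## Periodicity and regularity

The one-sided FFT amplitude spectrum of the mean-removed channel is
zero-padded ×16 by default: an hour at 1 Hz gives a native bin spacing of
~0.28 mHz, too coarse to separate 8 min (2.08 mHz) from 14 min (1.19 mHz)
periods; padding refines peak *localisation* (it interpolates, it does not
add resolution).  The dominant frequency is the largest magnitude within the
search band, default 0.0008–0.004 Hz — slightly wider than the nominal
slow-wave band so that both ~16 min and ~8 min periods sit comfortably
inside it.  Ties break toward the lower frequency.

The regularity index is 100 × (band peak magnitude) / (trapezoidal area of
the full one-sided spectrum over bin index).  It is invariant to amplitude
scaling and DC offset, and decreases as period jitter spreads the spectral
peak.  Its absolute value depends on record length, padding factor and the
noise floor, so it should be compared across groups within one pipeline
configuration, not across configurations.  Per-animal pooling averages the
three reported channels (oxCCO, HbT, HbDiff): the ratio is computed per
channel first, then averaged; the pooled dominant frequency is the
reciprocal of the pooled period so the pair stays mutually consistent.

## Wavelet semblance

The complex-Morlet CWT is computed in the frequency domain (Torrence &
Compo 1998): for scale s the daughter wavelet's transform is
`sqrt(2πs/dt)·π^(−1/4)·H(ω)·exp(−(sω − ω₀)²/2)`, and scales map to Fourier
frequencies by `f = (ω₀ + sqrt(2 + ω₀²))/(4πs)`.  The centre-frequency
parameter ω₀ = 6 is the standard time/frequency compromise (admissible in
practice); the grid is 64 log-spaced voices over 0.0005–0.01 Hz.  Results
are robust across ±1 octave of voice density (tested: 32 vs 128 voices move
a mean semblance by <0.02).

Semblance is computed from the cross-wavelet argument,
`S = Re(W_a·conj(W_b)) / |W_a·conj(W_b)|`, clipped to [−1, 1] against
roundoff.  Cells with cross power below 10⁻¹² of the field maximum have no
defined phase and are flagged NaN rather than contributing noise-driven ±1
values.

At millihertz frequencies the cone of influence (e-folding time √2·s)
covers much of a one-hour record.  The default summary averages over the
full record — matching the convention of averaging the whole hour — but the
COI-masked mean over interior cells is always reported alongside, and the
two should be compared before interpreting weak coupling.

Map renderings (time × period, diverging colour scale at −1/0/+1, y-axis
zoomed to period ± 50 s) are side outputs only; no analysis reads them.

## Group statistics

Two-sided Wilcoxon rank-sum tests with midranks.  For combined n ≤ 20 the
p-value is exact: all C(n, n_a) rank assignments are enumerated and
`p = P(|W − E W| ≥ |w_obs − E W|)` under the permutation null — at cohort
sizes of 4–9 animals the normal approximation is not trustworthy and the
enumeration is cheap.  Above n = 20 the normal approximation with tie and
continuity corrections is used (within 0.02 of exact at the boundary,
tested).  Summaries are mean ± SE (sample SD / √n).  No multiple-testing
correction is applied, matching the source analysis; the number of
uncorrected contrasts is always reported in the output and manifest.

## Synthetic cohort generator

Each synthetic animal is built from one shared slow-wave oscillator:

    φ[n+1] = φ[n] + 2πf·dt · (1 + σ·sqrt(fs/f)·η[n]),   η ~ N(0, 1)
    x_c[n] = A_c · sin(φ[n] + θ_c) + drift_c(n/N) + ε_c[n]

- The phase walk is **shared across channels**, so the inter-channel lags
  θ_c stay exact under jitter — emulating one physiological oscillator read
  out through several chromophores.
- The per-sample step SD is scaled by √(samples per cycle) so that σ is the
  **cycle-to-cycle fractional period SD**, the quantity the presets name.
  An unscaled per-sample walk would attenuate cycle-level jitter ~22× at
  these sampling ratios and produce no visible spectral broadening.
- Drift is a polynomial (order ≤ 6) in normalised time, hence exactly
  removable by the pipeline's detrend; default coefficients give a few µM
  of slow wander over the hour.
- Noise streams are spawned per channel from one master seed
  (`numpy.random.SeedSequence`), making output bitwise deterministic.

Preset parameters (1 h at 1 Hz, amplitudes oxCCO 0.15 / HbO₂ 0.8 / HHb
1.0 µM, noise 0.05 µM):

| group      | period (s) | jitter σ | HbO₂ lag (rad) | HHb lag (rad) |
|------------|-----------:|---------:|---------------:|--------------:|
| young_C57  |        480 |     0.02 |            0.0 |           0.0 |
| old_C57    |        840 |     0.12 |           −0.9 |          −0.2 |
| young_CFH  |        960 |     0.16 |           −0.6 |          −0.2 |
| old_CFH    |        960 |     0.20 |           −1.1 |          −0.3 |

Periods follow the reported group means (8 / 14 / 16 / 16 min); jitters
increase monotonically so regularity degrades in the same order; the growing
HbO₂ lag reproduces the loss of oxygenated-blood/metabolism phase locking in
aged and knockout groups.  HHb's amplitude exceeds HbO₂'s, so the derived
HbDiff sits near antiphase with oxCCO, as observed.  Noise SD and drift
magnitude are plausibility choices — the instrument's noise floor is not
characterised publicly — and amplitudes reflect the ~10× concentration
ratio of haemoglobin to cytochrome-c-oxidase.

**What the generator does not emulate**: animal-to-animal baseline
physiology differences beyond seed-driven jitter realisations, cardiac or
respiratory components, motion artefacts, photon-transport effects, or any
eye geometry.  A green test therefore establishes that the *analysis chain*
recovers known ground truth under the stated noise model — not that the
biological effect sizes would replicate in vivo.

## Numerical choices and degenerate inputs

- FFT-domain CWT pads to the next power of two; edge wraparound is covered
  by the reported COI.
- Flat (all-zero) spectra, empty search bands, non-uniform time axes, NaNs,
  rank-deficient designs and non-positive intensities all raise typed
  errors naming the offending quantity; nothing is silently imputed.
- Degenerate rank-sum input (all values identical) returns p = 1 with a
  warning rather than an error.
- Pipeline reruns under one seed are byte-identical; the config hash
  excludes presentation-only fields (output directory, figure toggle).

## Known limitations

- Absolute concentration scale depends on the unestablished mouse-eye DPF.
- The regularity index's absolute value is configuration-dependent (record
  length, padding, window); only within-configuration comparisons are
  meaningful.
- Sidedness of the original pairwise tests is not documented; two-sided is
  used as the conservative default.
- Wavelet coherence, red-noise significance testing and multitaper spectral
  estimation are deliberately out of scope.
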