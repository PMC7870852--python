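"""Generate one synthetic animal per cohort and inspect the ground truth.

Each preset encodes a group's slow-wave phenotype: the oscillation period
(480 s young controls up to 960 s knockouts), the cycle-to-cycle period
jitter (regularity), and the phase lag of each haemoglobin channel relative
to the mitochondrial oxCCO signal.
"""

from nirsosc import COHORT_NAMES, cohort_preset, generate_concentration_series

for name in COHORT_NAMES:
    preset = cohort_preset(name, seed=1)
    series = generate_concentration_series(preset.spec).with_composites()
    gt = series.metadata["synthetic"]
    print(
        f"{name:>10s}: period {gt['period_s']:5.0f} s, "
        f"jitter {gt['period_jitter_sd']:.2f}, "
        f"noise {gt['noise_sd']:.2f} uM, "
        f"channels {sorted(series.channels)}"
    )

# period_s is the true oscillation period the analysis stages must recover;
# jitter is the fractional cycle-to-cycle period s.d. that degrades the
# regularity index in the older / knockout groups.
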