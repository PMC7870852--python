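"""Forward Beer-Lambert model and the UCLn least-squares inversion.

Simulates broadband attenuation spectra (120 NIR wavelengths) from known
chromophore concentrations, then unmixes them back.  Noiseless recovery is
exact to numerical precision; with measurement noise the multiwavelength
least-squares fit stays unbiased.
"""

import numpy as np

from nirsosc import (
    OscillationSpec,
    PathlengthModel,
    generate_attenuation_series,
    generate_concentration_series,
    synthetic_extinction_table,
    ucln_unmix,
)

table = synthetic_extinction_table(n_wavelengths=120)
path = PathlengthModel(geometric_distance=1.0, dpf=1.0)
conc = generate_concentration_series(OscillationSpec(duration=600.0))

clean = generate_attenuation_series(conc, table, path)
recovered = ucln_unmix(clean, table, path)
for ch in ("oxCCO", "HbO2", "HHb"):
    err = np.abs(recovered[ch] - conc[ch]).max()
    print(f"noiseless {ch:>5s}: max recovery error {err:.2e} uM")

noise_sd = float(np.sqrt(np.mean(clean.values**2))) / 20.0  # SNR 20
noisy = generate_attenuation_series(conc, table, path, noise_sd, seed=0)
recovered = ucln_unmix(noisy, table, path)
for ch in ("oxCCO", "HbO2", "HHb"):
    rmse = np.sqrt(np.mean((recovered[ch] - conc[ch]) ** 2))
    print(f"SNR 20    {ch:>5s}: recovery RMSE {rmse:.3f} uM")

# The noiseless errors are at float precision: the forward model and the
# inversion are exactly consistent.  Under noise the error stays small
# because >100 wavelengths average the per-wavelength noise down.
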