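"""Beer–Lambert attenuation, the UCLn least-squares fit, and its round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsosc import (
    AttenuationSeries,
    ChannelError,
    ConditioningError,
    DataFormatError,
    ExtinctionTable,
    OscillationSpec,
    PathlengthModel,
    attenuation_change,
    generate_attenuation_series,
    generate_concentration_series,
    ucln_unmix,
)

CHROMOPHORES = ("oxCCO", "HbO2", "HHb")


class TestAttenuationChange:
    def test_identity_spectra_give_zero(self):
        ref = np.array([100.0, 200.0, 50.0])
        out = attenuation_change(np.tile(ref, (5, 1)), ref)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_tenfold_drop_is_one_od(self):
        ref = np.array([100.0, 100.0])
        intensity = np.array([[100.0, 10.0]])
        out = attenuation_change(intensity, ref)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]], atol=1e-15)

    def test_matches_log_ratio_oracle(self):
        rng = np.random.default_rng(42)
        ref = rng.uniform(50, 500, 30)
        intensity = rng.uniform(50, 500, (20, 30))
        out = attenuation_change(intensity, ref)
        np.testing.assert_allclose(
            out.values, np.log10(ref[None, :] / intensity), atol=1e-12, rtol=0
        )

    def test_nonpositive_intensity_locates_cell(self):
        ref = np.array([10.0, 10.0])
        intensity = np.array([[10.0, 10.0], [10.0, -1.0]])
        with pytest.raises(DataFormatError, match="time index 1, wavelength index 1"):
            attenuation_change(intensity, ref)


class TestUclnUnmix:
    def test_hand_invertible_three_by_three(self):
        # eps chosen so the 3x3 system inverts by hand: det = 2
        eps = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
        table = ExtinctionTable(np.array([780.0, 800.0, 820.0]), eps, CHROMOPHORES)
        truth = np.array([1.0, 2.0, 3.0])  # µM
        atten = AttenuationSeries(
            np.array([0.0, 1.0]),
            table.wavelengths,
            np.tile(eps @ truth * 1e-3, (2, 1)),
        )
        conc = ucln_unmix(atten, table, PathlengthModel(1.0, 1.0))
        for name, expected in zip(CHROMOPHORES, truth):
            np.testing.assert_allclose(conc[name], expected, atol=1e-10)

    def test_zero_attenuation_gives_zero_concentration(self, extinction_table):
        atten = AttenuationSeries(
            np.arange(4.0), extinction_table.wavelengths, np.zeros((4, 120))
        )
        conc = ucln_unmix(atten, extinction_table)
        for name in CHROMOPHORES:
            np.testing.assert_array_equal(conc[name], 0.0)

    def test_forward_then_unmix_round_trip(self, extinction_table, unit_pathlength):
        spec = OscillationSpec(duration=600.0, noise_sd=0.0, period_jitter_sd=0.0)
        conc = generate_concentration_series(spec)
        atten = generate_attenuation_series(conc, extinction_table, unit_pathlength)
        back = ucln_unmix(atten, extinction_table, unit_pathlength)
        for name in CHROMOPHORES:
            np.testing.assert_allclose(back[name], conc[name], atol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(-5, 5, allow_nan=False),
        beta=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, extinction_table, alpha, beta, seed):
        """unmix(a*dA1 + b*dA2) == a*unmix(dA1) + b*unmix(dA2)."""
        rng = np.random.default_rng(seed)
        t = np.arange(3.0)
        wl = extinction_table.wavelengths
        a1 = rng.normal(0, 0.01, (3, wl.size))
        a2 = rng.normal(0, 0.01, (3, wl.size))
        mix = AttenuationSeries(t, wl, alpha * a1 + beta * a2)
        c_mix = ucln_unmix(mix, extinction_table)
        c1 = ucln_unmix(AttenuationSeries(t, wl, a1), extinction_table)
        c2 = ucln_unmix(AttenuationSeries(t, wl, a2), extinction_table)
        for name in CHROMOPHORES:
            np.testing.assert_allclose(
                c_mix[name], alpha * c1[name] + beta * c2[name], atol=1e-9
            )

    def test_rank_deficient_design_reports_condition(self):
        eps = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [1.0, 1.0, 1.0], [0.5, 0.5, 0.5]])
        with pytest.raises(ConditioningError):
            ExtinctionTable(np.array([780.0, 790.0, 800.0, 810.0]), eps, CHROMOPHORES)

    def test_missing_wavelengths_rejected(self, extinction_table):
        atten = AttenuationSeries(np.arange(2.0), np.array([1000.0, 1010.0, 1020.0]), np.zeros((2, 3)))
        with pytest.raises(DataFormatError, match="absent from extinction table"):
            ucln_unmix(atten, extinction_table)


class TestForwardModel:
    def test_zero_concentration_gives_zero_attenuation(self, extinction_table, unit_pathlength):
        from nirsosc import ChromophoreTimeSeries

        conc = ChromophoreTimeSeries(
            np.arange(5.0), {c: np.zeros(5) for c in CHROMOPHORES}
        )
        atten = generate_attenuation_series(conc, extinction_table, unit_pathlength)
        np.testing.assert_array_equal(atten.values, 0.0)

    def test_single_chromophore_identity(self):
        from nirsosc import ChromophoreTimeSeries

        table = ExtinctionTable(np.array([800.0]), np.array([[1000.0]]), ("oxCCO",))
        conc = ChromophoreTimeSeries(np.arange(2.0), {"oxCCO": np.array([0.5, 0.5])})
        atten = generate_attenuation_series(conc, table, PathlengthModel(1.0, 1.0))
        # eps=1000 mM^-1 cm^-1 x 0.5 µM x 1 cm = 0.5 OD
        np.testing.assert_allclose(atten.values, 0.5, atol=1e-15)

    def test_channel_mismatch_named(self, extinction_table, unit_pathlength):
        from nirsosc import ChromophoreTimeSeries

        conc = ChromophoreTimeSeries(np.arange(3.0), {"oxCCO": np.zeros(3)})
        with pytest.raises(ChannelError, match="HbO2"):
            generate_attenuation_series(conc, extinction_table, unit_pathlength)


class TestExtinctionTableIO:
    def test_log_base_e_converted(self, tmp_path):
        p = tmp_path / "ext_e.tsv"
        p.write_text(
            "# log_base: e\nwavelength_nm\tHbO2\tHHb\toxCCO\n"
            "780\t2.302585092994046\t1.0\t0.5\n"
            "800\t1.0\t2.302585092994046\t0.7\n"
            "820\t0.3\t0.9\t2.302585092994046\n"
        )
        table = ExtinctionTable.read(p)
        assert table.coefficients[0, 0] == pytest.approx(1.0)

    def test_write_read_round_trip(self, tmp_path, extinction_table):
        p = tmp_path / "ext.tsv"
        extinction_table.write(p)
        back = ExtinctionTable.read(p)
        np.testing.assert_allclose(back.coefficients, extinction_table.coefficients, rtol=1e-12)
        assert back.chromophore_names == extinction_table.chromophore_names
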