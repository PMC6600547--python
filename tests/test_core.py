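"""Data containers, CSV round-trips, and the point operations of the core module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    Spectrum,
    Titration,
    inner_filter_correct,
    peak_locate,
    percent_quench,
    read_titration_table,
    stokes_shift,
    write_titration_table,
)


class TestTitrationIO:
    def test_csv_schema_roundtrip(self, tmp_path, noiseless_titration):
        path = tmp_path / "titration.csv"
        write_titration_table(noiseless_titration, path)
        back = read_titration_table(path, temperature=noiseless_titration.temperature)
        assert len(back) == 8
        assert back.quencher_conc[0] == 0.0
        np.testing.assert_allclose(back.quencher_conc, noiseless_titration.quencher_conc, rtol=1e-12)
        np.testing.assert_allclose(back.intensity, noiseless_titration.intensity, rtol=1e-12)
        assert back.temperature == noiseless_titration.temperature

    def test_absorbance_columns_roundtrip(self, tmp_path, conc_grid):
        tit = Titration(
            conc_grid,
            np.linspace(1000, 800, 8),
            298.0,
            absorbance_ex=np.full(8, 0.05),
            absorbance_em=np.full(8, 0.02),
        )
        path = tmp_path / "t.csv"
        write_titration_table(tit, path)
        back = read_titration_table(path)
        np.testing.assert_allclose(back.absorbance_ex, tit.absorbance_ex)
        np.testing.assert_allclose(back.absorbance_em, tit.absorbance_em)

    def test_read_errors(self, tmp_path):
        bad_cols = tmp_path / "bad.csv"
        bad_cols.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="column"):
            read_titration_table(bad_cols)
        dup = tmp_path / "dup.csv"
        dup.write_text("conc_uM,intensity\n0,1000\n8,950\n8,940\n")
        with pytest.raises(ValueError, match="increasing"):
            read_titration_table(dup)
        neg = tmp_path / "neg.csv"
        neg.write_text("conc_uM,intensity\n0,1000\n8,-5\n")
        with pytest.raises(ValueError, match="positive"):
            read_titration_table(neg)

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("# instrument dump\nconc_uM,intensity\n0,1000\n# mid-file note\n8,950\n16,900\n")
        assert len(read_titration_table(path)) == 3

    @pytest.mark.parametrize("unit,factor", [("uM", 1e-6), ("mM", 1e-3), ("M", 1.0)])
    def test_concentration_units(self, tmp_path, unit, factor):
        path = tmp_path / "u.csv"
        path.write_text("conc_uM,intensity\n0,1000\n2,950\n4,900\n")
        tit = read_titration_table(path, conc_unit=unit)
        assert tit.quencher_conc[1] == pytest.approx(2 * factor)


class TestTitrationInvariants:
    def test_requires_zero_first_point(self, conc_grid):
        with pytest.raises(ValueError, match=r"\[Q\] = 0"):
            Titration(conc_grid + 1e-6, np.linspace(1000, 800, 8), 298.0)

    def test_f0_is_first_intensity(self, noiseless_titration):
        assert noiseless_titration.f0 == noiseless_titration.intensity[0]

    def test_corrected_applies_inner_filter(self, conc_grid):
        f = np.linspace(1000, 800, 8)
        tit = Titration(
            conc_grid, f, 298.0,
            absorbance_ex=np.full(8, 0.1), absorbance_em=np.full(8, 0.05),
        )
        np.testing.assert_allclose(tit.corrected().intensity, f * 10**0.075)

    def test_corrected_noop_without_absorbances(self, noiseless_titration):
        assert noiseless_titration.corrected() is noiseless_titration


class TestInnerFilter:
    @pytest.mark.parametrize(
        "f_obs,a_ex,a_em,expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.1, 0.05, 118.85022274370183),
            (0.0, 0.3, 0.3, 0.0),
        ],
    )
    def test_values(self, f_obs, a_ex, a_em, expected):
        assert inner_filter_correct(f_obs, a_ex, a_em) == pytest.approx(expected, rel=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            inner_filter_correct(100.0, -0.1, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 2),
        b=st.floats(0, 2),
        delta=st.floats(1e-6, 1.0),
    )
    def test_monotone_in_each_absorbance(self, a, b, delta):
        base = inner_filter_correct(100.0, a, b)
        assert inner_filter_correct(100.0, a + delta, b) > base
        assert inner_filter_correct(100.0, a, b + delta) > base


class TestSpectralMetrics:
    @pytest.mark.parametrize(
        "f0,f,expected",
        [(3348.0, 2847.0, 14.96), (7150.0, 5888.0, 17.65)],
    )
    def test_synchronous_quench_percentages(self, f0, f, expected):
        assert percent_quench(f0, f) == pytest.approx(expected, abs=0.005)

    def test_no_quenching_is_zero(self):
        assert percent_quench(123.4, 123.4) == 0.0

    def test_f0_must_be_positive(self):
        with pytest.raises(ValueError):
            percent_quench(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(q=st.floats(-50, 100), f0=st.floats(1e-3, 1e6))
    def test_quench_inversion(self, q, f0):
        assert percent_quench(f0, f0 * (1 - q / 100.0)) == pytest.approx(q, abs=1e-6)

    @pytest.mark.parametrize("ex,em,expected", [(280.0, 335.0, 55.0), (230.0, 327.0, 97.0)])
    def test_stokes_shift_values(self, ex, em, expected):
        assert stokes_shift(ex, em) == expected

    def test_stokes_shift_zero_at_equal_wavelengths(self):
        assert stokes_shift(300.0, 300.0) == 0.0


class TestPeakLocate:
    def test_gaussian_peak(self):
        wl = np.arange(300.0, 401.0)
        spec = Spectrum(wl, 50 * np.exp(-0.5 * ((wl - 340) / 10) ** 2))
        assert peak_locate(spec) == (340.0, 50.0)

    def test_tie_breaks_to_lowest_wavelength(self):
        wl = np.array([320.0, 330.0, 340.0, 345.0, 350.0])
        spec = Spectrum(wl, np.array([1.0, 5.0, 2.0, 5.0, 1.0]))
        assert peak_locate(spec) == (330.0, 5.0)

    def test_monotone_decreasing_returns_first_point(self):
        wl = np.arange(300.0, 310.0)
        spec = Spectrum(wl, np.linspace(10, 1, 10))
        assert peak_locate(spec)[0] == 300.0

    def test_spectrum_invariants(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([300.0, 300.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            Spectrum(np.array([300.0, 310.0]), np.array([1.0, -2.0]), kind="extinction")
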