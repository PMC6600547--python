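"""Stern-Volmer fits, mechanism classification, and van't Hoff thermodynamics."""

import numpy as np
import pytest

from specbind import (
    Titration,
    bimolecular_rate,
    classify_quenching,
    gibbs_from_k,
    modified_sv_fit,
    stern_volmer_fit,
    vant_hoff_fit,
)
from specbind.constants import R_KCAL
from specbind.synthetic import simulate_quenching_series

TAU0 = 5.71e-9


class TestSternVolmer:
    def test_noiseless_slope_recovery(self, noiseless_titration):
        fit = stern_volmer_fit(noiseless_titration)
        assert fit.ksv == pytest.approx(2670.0, rel=1e-6)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.kq == pytest.approx(2670.0 / TAU0, rel=1e-6)

    def test_constant_intensity_gives_zero_ksv(self, conc_grid):
        tit = Titration(conc_grid, np.full(8, 500.0), 298.0)
        assert stern_volmer_fit(tit).ksv == pytest.approx(0.0, abs=1e-9)

    def test_noisy_estimate_within_three_se(self):
        tits, _ = simulate_quenching_series(
            ksv_by_temperature={298.0: 2670.0}, noise_sd=0.01, seed=11
        )
        fit = stern_volmer_fit(tits[298.0])
        assert abs(fit.ksv - 2670.0) < 3 * fit.std_errors["ksv"]

    def test_too_few_points_rejected(self):
        tit = Titration(np.array([0.0, 1e-5]), np.array([1000.0, 950.0]), 298.0)
        with pytest.raises(ValueError, match="at least 3"):
            stern_volmer_fit(tit)


class TestBimolecularRate:
    @pytest.mark.parametrize(
        "ksv,expected_1e11",
        [(2.67e3, 4.68), (2.10e3, 3.68), (1.63e3, 2.85), (1.27e3, 2.22)],
    )
    def test_quenching_rate_constants(self, ksv, expected_1e11):
        assert bimolecular_rate(ksv, TAU0) / 1e11 == pytest.approx(expected_1e11, abs=0.01)

    def test_zero_ksv(self):
        assert bimolecular_rate(0.0, TAU0) == 0.0

    def test_invalid_lifetime(self):
        with pytest.raises(ValueError):
            bimolecular_rate(1e3, 0.0)


class TestModifiedSternVolmer:
    def test_static_1to1_identity(self, conc_grid):
        # for pure 1:1 static quenching, (F0-F)/F = Ksv[Q], so Kb = Ksv and n = 1
        f = 1000.0 / (1.0 + 1690.0 * conc_grid)
        fit = modified_sv_fit(Titration(conc_grid, f, 298.0))
        assert fit.kb == pytest.approx(1690.0, rel=1e-9)
        assert fit.n == pytest.approx(1.0, abs=1e-9)

    def test_double_log_inverse_recovery(self, conc_grid):
        # generate directly in the double-log form with non-unit stoichiometry
        kb, n = 8.42e3, 1.18
        f0 = 1000.0
        f = np.concatenate([[f0], f0 / (1.0 + kb * conc_grid[1:] ** n)])
        fit = modified_sv_fit(Titration(conc_grid, f, 315.0))
        assert fit.kb == pytest.approx(kb, rel=1e-9)
        assert fit.n == pytest.approx(n, rel=1e-9)

    def test_two_quenched_points_rejected(self):
        tit = Titration(np.array([0.0, 1e-5, 2e-5]), np.array([1000.0, 950.0, 900.0]), 298.0)
        with pytest.raises(ValueError, match="at least 3"):
            modified_sv_fit(tit)

    def test_unquenched_point_rejected(self, conc_grid):
        f = 1000.0 / (1.0 + 1690.0 * conc_grid)
        f[3] = 1000.0  # F == F0 makes the log undefined
        with pytest.raises(ValueError, match="F < F0"):
            modified_sv_fit(Titration(conc_grid, f, 298.0))


class TestClassifyQuenching:
    def _fits(self, ksv_by_t, tau0=TAU0):
        fits = []
        for t in sorted(ksv_by_t):
            tits, _ = simulate_quenching_series(ksv_by_temperature={t: ksv_by_t[t]})
            fits.append(stern_volmer_fit(tits[t], tau0=tau0))
        return fits

    def test_albumin_series_is_static(self, ksv_by_t):
        assert classify_quenching(self._fits(ksv_by_t)) == "static"

    def test_increasing_ksv_below_limit_is_dynamic(self):
        fits = self._fits({298.0: 1.0, 310.0: 2.0}, tau0=1e-9)  # kq ~ 1e9-2e9
        assert classify_quenching(fits) == "dynamic"

    def test_non_monotone_is_indeterminate(self):
        fits = self._fits({298.0: 2.0e3, 303.0: 1.0e3, 310.0: 1.5e3})
        assert classify_quenching(fits) == "indeterminate"

    def test_single_temperature_rejected(self):
        fits = self._fits({298.0: 2.67e3})
        with pytest.raises(ValueError):
            classify_quenching(fits)


class TestVantHoff:
    def test_albumin_thermodynamics(self, kb_by_t):
        res = vant_hoff_fit(sorted(kb_by_t.items()))
        # printed-table agreement within the reported triplicate SDs
        assert res.dh == pytest.approx(16.34, abs=0.96)
        assert 298.0 * res.ds == pytest.approx(20.73, abs=1.32)
        assert res.dg(298.0) == pytest.approx(-4.39, abs=0.63)

    def test_constant_kb_gives_zero_enthalpy(self):
        res = vant_hoff_fit([(298.0, 2.0e3), (305.0, 2.0e3), (312.0, 2.0e3)])
        assert res.dh == pytest.approx(0.0, abs=1e-9)
        assert res.dg(298.0) == pytest.approx(-R_KCAL * 298.0 * np.log(2.0e3), rel=1e-9)

    def test_noiseless_inverse_recovery(self):
        dh, ds = 16.34, 0.0696
        temps = [298.0, 303.0, 310.0, 315.0]
        pts = [(t, np.exp(-dh / (R_KCAL * t) + ds / R_KCAL)) for t in temps]
        res = vant_hoff_fit(pts)
        assert res.dh == pytest.approx(dh, rel=1e-12)
        assert res.ds == pytest.approx(ds, rel=1e-12)

    def test_dg_table_identity(self, kb_by_t):
        res = vant_hoff_fit(sorted(kb_by_t.items()))
        tbl = res.table
        np.testing.assert_allclose(
            tbl["dG_kcal_mol"], res.dh - tbl["T_K"] * res.ds, rtol=0, atol=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="distinct"):
            vant_hoff_fit([(298.0, 1e3), (298.0, 2e3), (310.0, 3e3)])
        with pytest.raises(ValueError, match="positive"):
            vant_hoff_fit([(298.0, 1e3), (303.0, -2e3), (310.0, 3e3)])
        with pytest.raises(ValueError, match="at least 3"):
            vant_hoff_fit([(298.0, 1e3), (303.0, 2e3)])


class TestGibbs:
    def test_association_free_energies(self):
        assert gibbs_from_k(1.69e3, 298.0) == pytest.approx(-4.40, abs=0.005)
        assert gibbs_from_k(2.1e3, 298.0) == pytest.approx(-4.53, abs=0.005)

    def test_unit_constant_gives_zero(self):
        assert gibbs_from_k(1.0, 310.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gibbs_from_k(-1.0, 298.0)
        with pytest.raises(ValueError):
            gibbs_from_k(1e3, 0.0)


class TestStochasticRecovery:
    def test_median_ksv_error_under_five_percent(self):
        """200 seeded 1%-noise replicates keep the median relative Ksv error < 5%."""
        errs = []
        for seed in range(200):
            tits, _ = simulate_quenching_series(
                ksv_by_temperature={298.0: 2670.0}, noise_sd=0.01, seed=seed
            )
            fit = stern_volmer_fit(tits[298.0])
            errs.append(abs(fit.ksv - 2670.0) / 2670.0)
        assert np.median(errs) < 0.05
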