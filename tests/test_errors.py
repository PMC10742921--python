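"""Residuals, EAR, the standard-error formula, ESE and misfit."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import raschmf as rm
from raschmf.errors import EPS_FLOOR
from raschmf.exceptions import DimensionMismatchError


class TestResiduals:
    def test_exact_fit_is_zero(self):
        x = np.ones((3, 3))
        assert np.allclose(rm.residuals(x, x), 0.0)

    def test_single_cell(self):
        assert rm.residuals(np.array([[1.0]]), np.array([[0.25]]))[0, 0] == 0.75

    def test_missing_stays_missing(self):
        x = np.array([[1.0, np.nan]])
        res = rm.residuals(x, np.zeros((1, 2)))
        assert res[0, 0] == 1.0 and np.isnan(res[0, 1])

    def test_column_means_near_zero_on_ls_fit(self, noisy_random):
        dm, _ = noisy_random
        cs = rm.als_decompose(dm, 4, seed=0, tol=1e-9, max_iter=100)
        res = rm.residuals(dm, cs.estimates)
        col_means = np.nanmean(res, axis=0)
        assert np.nanmax(np.abs(col_means)) < 0.2  # sampling noise only


class TestEstimateEAR:
    def test_homoscedastic_scale(self):
        """EAR estimates the RMS residual scale of homoscedastic noise."""
        rng = np.random.default_rng(0)
        res = 0.5 * rng.standard_normal((300, 80))
        ear, (rc, cc), coefs = rm.estimate_ear(res, seed=1)
        assert 0.4 < np.median(ear) < 0.6
        assert rc.shape == (300, 2) and cc.shape == (2, 80)

    def test_row_noise_ratio_recovered(self):
        """Rows at sd 1.0 vs 0.5 show up as a ~2x EAR ratio."""
        rng = np.random.default_rng(1)
        res = np.vstack([1.0 * rng.standard_normal((150, 80)),
                         0.5 * rng.standard_normal((150, 80))])
        ear, _, _ = rm.estimate_ear(res, seed=1)
        ratio = np.median(ear[:150]) / np.median(ear[150:])
        assert 1.6 < ratio < 2.4

    def test_exact_fit_floors(self):
        ear, _, _ = rm.estimate_ear(np.zeros((20, 10)), seed=0)
        assert np.all(ear <= 10 * np.sqrt(EPS_FLOOR))


class TestStandardError:
    def test_direct_evaluation(self):
        # 2 * 1 * sqrt(2) / ((38-2)(38-2))^(1/4) = 2.8284 / 6
        assert rm.standard_error(1.0, 38, 38, 2) == pytest.approx(2 * np.sqrt(2) / 6,
                                                                  abs=1e-4)
        assert rm.standard_error(1.0, 38, 38, 2) == pytest.approx(0.4714, abs=1e-4)

    def test_infinite_at_r_equals_d(self):
        assert np.isinf(rm.standard_error(1.0, 2, 38, 2))
        assert np.isinf(rm.standard_error(1.0, 38, 2, 2))

    def test_one_facet_reduction(self):
        assert rm.one_facet_se(1.0, 26) == pytest.approx(1 / 5)
        assert np.isinf(rm.one_facet_se(1.0, 1))

    def test_invalid_counts(self):
        with pytest.raises(DimensionMismatchError):
            rm.standard_error(1.0, 1, 38, 2)

    def test_monotonicity(self):
        """SE decreases in r and c, increases in ear and d."""
        base = rm.standard_error(1.0, 30, 40, 3)
        assert rm.standard_error(1.0, 60, 40, 3) < base
        assert rm.standard_error(1.0, 30, 80, 3) < base
        assert rm.standard_error(2.0, 30, 40, 3) > base
        assert rm.standard_error(1.0, 30, 40, 4) > base

    def test_legacy_formula_option(self):
        """Same numerator, (r-1)(c-1) denominator."""
        legacy = rm.standard_error(1.0, 38, 38, 2, formula="legacy")
        assert legacy == pytest.approx(2.0 * np.sqrt(2) / (37 * 37) ** 0.25)
        assert legacy != rm.standard_error(1.0, 38, 38, 2)


class TestEstimateESE:
    def test_constant_se_recovered(self):
        rng = np.random.default_rng(2)
        se = np.full((60, 30), 0.8)
        se += 1e-6 * rng.standard_normal(se.shape)  # break exact degeneracy
        ese, (rc, cc), _ = rm.estimate_ese(se, seed=0)
        assert np.median(np.abs(ese - 0.8)) < 0.08

    def test_coordinates_are_two_dimensional(self, noisy_random):
        dm, _ = noisy_random
        cs = rm.als_decompose(dm, 4, seed=0, max_iter=60)
        model = rm.ResidualErrorModel(seed=1).fit(dm, cs.estimates, 4)
        nm = model.noise_model_
        assert nm.se_row_coords.shape[1] == 2
        assert nm.se_col_coords.shape[0] == 2
        assert nm.ear_row_coords.shape[1] == 2

    def test_ese_tracks_se(self, noisy_random):
        dm, _ = noisy_random
        cs = rm.als_decompose(dm, 4, seed=0, max_iter=60)
        nm = rm.ResidualErrorModel(seed=1).fit(dm, cs.estimates, 4).noise_model_
        finite = np.isfinite(nm.se) & np.isfinite(nm.ese)
        r, _ = pearsonr(nm.se[finite].ravel(), nm.ese[finite].ravel())
        assert r > 0.9


class TestMisfit:
    def test_exact_fit_all_interpretable(self):
        x = np.random.default_rng(3).standard_normal((10, 8))
        report = rm.misfit(x, x, np.ones_like(x))
        assert np.allclose(report.cell, 0.0)
        assert report.person_interpretable.all()
        assert report.frac_large == 0.0

    def test_cell_standardization(self):
        x = np.zeros((1, 1))
        e = np.array([[-1.0]])  # residual = 1.0 with ear 0.5 -> misfit 2
        report = rm.misfit(x, e, np.array([[0.5]]))
        assert report.cell[0, 0] == pytest.approx(2.0)

    def test_mean_square_near_one_when_standardized(self):
        """Gaussian residuals over their true sd have unit mean-square misfit."""
        rng = np.random.default_rng(4)
        sd = 0.7
        x = sd * rng.standard_normal((400, 150))
        report = rm.misfit(x, np.zeros_like(x), np.full_like(x, sd))
        ms = np.nanmean(report.cell**2)
        assert 0.9 < ms < 1.1


class TestSECalibration:
    def test_se_predicts_true_error(self, noisy_random):
        """median(|E-T| / SE) in [0.4, 2.0] and SE orders |E-T|."""
        dm, truth = noisy_random
        cs = rm.als_decompose(dm, 4, seed=2, tol=1e-8, max_iter=100, n_starts=2)
        nm = rm.ResidualErrorModel(seed=3).fit(dm, cs.estimates, 4).noise_model_
        err = np.abs(cs.estimates - truth.T)
        finite = np.isfinite(nm.se) & np.isfinite(err)
        assert 0.4 < np.median(err[finite] / nm.se[finite]) < 2.0
        from scipy.stats import spearmanr
        rho = spearmanr(nm.se[finite].ravel(), err[finite].ravel()).statistic
        assert rho > 0.2

    def test_bias_direction_at_noise_extremes(self):
        """Error overestimated at small noise, underestimated at large noise."""
        ratios = {}
        for label, noise in (("small", 0.1), ("large", 4.0)):
            spec = rm.SimulationSpec(n_persons=150, n_items=60, true_d=3,
                                     noise_base=noise, missing_fraction=0.1,
                                     missing_pattern="random",
                                     row_noise_spread=0.0, col_noise_spread=0.0)
            dm, truth = rm.simulate_dataset(spec, seed=21)
            cs = rm.als_decompose(dm, 3, seed=2, max_iter=60)
            nm = rm.ResidualErrorModel(seed=3).fit(dm, cs.estimates, 3).noise_model_
            err = np.abs(cs.estimates - truth.T)
            finite = np.isfinite(nm.se) & np.isfinite(err)
            ratios[label] = np.median(nm.se[finite] / err[finite])
        assert ratios["small"] > ratios["large"]
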