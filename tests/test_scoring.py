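"""Construct coordinates, the 0-100 scale, classification and person scoring."""

import numpy as np
import pytest

import raschmf as rm
from raschmf.exceptions import (
    InsufficientDataError,
    UncalibratedMetricError,
)
from raschmf.scoring import ScaleTransform


class TestConstructCoordinates:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal((50, 4))
        w_true = np.array([1.0, -0.5, 0.25, 2.0])
        w, stats = rm.construct_coordinates(r, r @ w_true)
        assert np.allclose(w, w_true, atol=1e-8)
        assert stats["rmse"] < 1e-8

    def test_orthonormal_basis_gives_projection(self):
        rng = np.random.default_rng(1)
        r = rm.orthonormalize(rng.standard_normal((60, 3)))
        y = rng.standard_normal(60)
        w, _ = rm.construct_coordinates(r, y)
        assert np.allclose(w, r.T @ y, atol=1e-8)

    def test_beats_grid_perturbations(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal((40, 2))
        y = r @ np.array([0.4, -0.9]) + 0.5 * rng.standard_normal(40)
        w, _ = rm.construct_coordinates(r, y)
        rss = np.sum((y - r @ w) ** 2)
        for dx in np.arange(-0.05, 0.051, 0.01):
            for dy in np.arange(-0.05, 0.051, 0.01):
                assert rss <= np.sum((y - r @ (w + [dx, dy])) ** 2) + 1e-12

    def test_insufficient_rated_persons(self):
        r = np.random.default_rng(3).standard_normal((10, 4))
        y = np.full(10, np.nan)
        y[:3] = 1.0
        with pytest.raises(InsufficientDataError):
            rm.construct_coordinates(r, y)


class TestDRS:
    def test_affine_contract(self):
        tr = ScaleTransform(semi_true_factor=1.0, mean=0.0, slope=10.0,
                            intercept=50.0, fitted=True)
        assert tr.apply(0.0) == pytest.approx(50.0)
        assert tr.apply(1.0) == pytest.approx(60.0)

    def test_ordering_preserved(self):
        rng = np.random.default_rng(4)
        est = np.sort(rng.standard_normal(30))
        drs, _ = rm.drs_from_estimates(est, np.abs(rng.standard_normal(30)) * 0.1)
        assert np.all(np.diff(drs) >= 0)

    def test_persisted_transform_round_trip(self):
        rng = np.random.default_rng(5)
        est = rng.standard_normal(50)
        ses = np.abs(rng.standard_normal(50)) * 0.2
        drs, tr = rm.drs_from_estimates(est, ses)
        replay, _ = rm.drs_from_estimates(est, ses, transform=tr)
        assert np.allclose(replay, drs, atol=1e-10)

    def test_percentile_anchoring(self):
        rng = np.random.default_rng(6)
        est = rng.standard_normal(2000)
        drs, tr = rm.drs_from_estimates(est, np.zeros(2000))
        assert np.percentile(drs, 1) == pytest.approx(10.0, abs=0.2)
        assert np.percentile(drs, 99) == pytest.approx(90.0, abs=0.2)

    def test_unfitted_transform_rejected(self):
        with pytest.raises(UncalibratedMetricError):
            rm.drs_from_estimates(np.zeros(5), transform=ScaleTransform())


class TestClassify:
    @pytest.mark.parametrize("drs,expected", [
        (47.0, "Low"),
        (60.0, "Severe"),
        (50.0, "Moderate"),   # half-open boundary
        (45.0, "Low"),
        (44.999, "None"),
        (-5.0, "None"),
        (120.0, "Severe"),
    ])
    def test_categories(self, drs, expected):
        assert rm.classify(drs) == expected

    def test_vectorized(self):
        assert rm.classify([30.0, 46.0, 52.0, 70.0]) == \
            ["None", "Low", "Moderate", "Severe"]


class TestScorePerson:
    def test_calibration_person_reproduced(self, instrument, fitted_model):
        """Rescoring a calibration person from the bank matches calibration."""
        dm, _, _, _ = instrument
        for n in (0, 17, 101):
            row = {cid: dm.values[n, j] for j, cid in enumerate(dm.col_ids)
                   if np.isfinite(dm.values[n, j])}
            ps = fitted_model.score_person(row)
            assert ps.drs == pytest.approx(fitted_model.drs_[n], abs=1e-6)
            assert ps.category == fitted_model.categories_[n]

    def test_disjoint_item_subsets_agree_without_noise(self):
        """Specific objectivity: any sufficient item subset gives the same score."""
        spec = rm.SimulationSpec(n_persons=150, n_items=60, true_d=4,
                                 noise_base=0.0, frac_dichotomous=0.0,
                                 frac_timing=0.0, age_blocks=False,
                                 missing_fraction=0.0, rating_noise=0.0)
        dm, truth, ages, ratings = rm.simulate_instrument(spec, seed=19)
        # complete-data pseudo-logits are column-centered (removing the
        # constant dimension) and age-projected, so the residual rank is
        # true_d - 2
        model = rm.RiskScaleModel(d_residual=2, seed=2, tol=1e-12,
                                  max_iter=400).fit(dm, ages, ratings)
        n = 5
        full = {cid: dm.values[n, j] for j, cid in enumerate(dm.col_ids)}
        even = {cid: v for k, (cid, v) in enumerate(full.items()) if k % 2 == 0}
        odd = {cid: v for k, (cid, v) in enumerate(full.items()) if k % 2 == 1}
        s_even = model.score_person(even)
        s_odd = model.score_person(odd)
        assert s_even.drs == pytest.approx(s_odd.drs, abs=1e-4)

    def test_too_few_responses(self, fitted_model):
        bank = fitted_model.bank_
        few = dict(list({i: 1.0 for i in bank.item_ids}.items())[: bank.dimensionality])
        with pytest.raises(InsufficientDataError):
            rm.score_person(few, bank)

    def test_unknown_items_skipped_with_warning(self, instrument, fitted_model):
        dm, _, _, _ = instrument
        row = {cid: dm.values[0, j] for j, cid in enumerate(dm.col_ids)
               if np.isfinite(dm.values[0, j])}
        row["mystery_item"] = 1.0
        with pytest.warns(UserWarning, match="mystery_item"):
            ps = fitted_model.score_person(row)
        assert ps.n_items_used == len(row) - 1

    def test_score_fields_complete(self, instrument, fitted_model):
        dm, _, _, _ = instrument
        row = {cid: dm.values[2, j] for j, cid in enumerate(dm.col_ids)
               if np.isfinite(dm.values[2, j])}
        d = fitted_model.score_person(row).to_dict()
        assert set(d) == {"drs", "se", "outfit", "category", "interpretable",
                          "n_items_used"}
        assert d["se"] > 0 and d["outfit"] >= 0

    def test_uninterpretable_rate_small_on_conforming_data(self, fitted_model):
        assert 1.0 - np.mean(fitted_model.interpretable_) < 0.15
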