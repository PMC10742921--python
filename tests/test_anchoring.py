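"""Age anchoring, common-item equating, item drift and the item bank."""

import numpy as np
import pytest

import raschmf as rm
from raschmf.exceptions import AssemblyError, DimensionMismatchError, EquatingError
from raschmf.scoring import ScaleTransform


def _split_form(dm, cols):
    return rm.DataMatrix(
        dm.values[:, cols], dm.row_ids, [dm.col_ids[j] for j in cols],
        {dm.col_ids[j]: dm.col_metrics[dm.col_ids[j]] for j in cols},
    )


def _bank_from(dm, d, seed=1):
    x_pl, metrics = dm.to_pseudologit()
    cs = rm.als_decompose(x_pl, d, seed=seed, tol=1e-12, max_iter=300)
    nm = rm.ResidualErrorModel(seed=seed).fit(x_pl.values, cs.estimates, d).noise_model_
    tr = ScaleTransform(1.0, 0.0, 10.0, 50.0, fitted=True)
    return rm.build_item_bank(cs, nm, metrics, np.ones(d), tr), cs, x_pl


@pytest.fixture(scope="module")
def age_instrument():
    spec = rm.SimulationSpec(n_persons=150, n_items=60, true_d=4, noise_base=0.0,
                             frac_dichotomous=0.0, frac_timing=0.0,
                             age_blocks=False)
    return rm.simulate_instrument(spec, seed=3)


class TestAgeAnchoring:
    def test_residuals_orthogonal_to_age(self, age_instrument):
        dm, truth, ages, _ = age_instrument
        x_pl, _ = dm.to_pseudologit()
        a, c1, res = rm.age_regression(x_pl.values, ages)
        x0 = np.where(np.isfinite(res), res, 0.0)
        assert np.max(np.abs(a @ x0)) < 1e-8

    def test_noise_free_oracle(self, age_instrument):
        """Calibration reproduces the truth on observed and missing cells."""
        dm, truth, ages, _ = age_instrument
        x_pl, _ = dm.to_pseudologit()
        cs = rm.age_anchored_calibration(x_pl, ages, 3, seed=5, tol=1e-12,
                                         refine_max_iter=300)
        m = dm.mask
        # pseudo-logit z-scores each column, so compare to column-standardized T
        tz = np.full_like(truth.T, np.nan)
        for j in range(truth.T.shape[1]):
            o = m[:, j]
            tz[:, j] = (truth.T[:, j] - truth.T[o, j].mean()) / truth.T[o, j].std()
        assert np.nanmax(np.abs(cs.estimates - tz)) < 1e-4
        assert cs.dimensionality == 4
        assert cs.anchored_dims == {0}

    def test_age_enters_only_through_first_loading(self, age_instrument):
        """Same residual coordinates, different ages: estimates differ by C[0]."""
        dm, truth, ages, _ = age_instrument
        x_pl, _ = dm.to_pseudologit()
        cs = rm.age_anchored_calibration(x_pl, ages, 3, seed=5, tol=1e-12,
                                         refine_max_iter=300)
        r = np.array(cs.R[0])
        r_alt = np.array(r)
        r_alt[0] += 0.5  # shift the age coordinate only
        diff = r_alt @ cs.C - r @ cs.C
        assert np.allclose(diff, 0.5 * cs.C[0], atol=1e-12)

    def test_invalid_age_listed(self, age_instrument):
        dm, _, ages, _ = age_instrument
        bad = np.array(ages)
        bad[3] = np.nan
        with pytest.raises(DimensionMismatchError, match=dm.row_ids[3]):
            rm.age_anchored_calibration(dm.to_pseudologit()[0], bad, 3)


@pytest.fixture(scope="module")
def forms():
    spec = rm.SimulationSpec(n_persons=120, n_items=60, true_d=3,
                             noise_base=0.0, missing_fraction=0.0)
    dm, truth = rm.simulate_dataset(spec, seed=9)
    form_a = _split_form(dm, list(range(40)))
    form_b = _split_form(dm, list(range(20, 60)))
    return dm, form_a, form_b


class TestEquating:
    def test_anchored_matches_joint_calibration(self, forms):
        dm, form_a, form_b = forms
        bank_a, _, _ = _bank_from(form_a, 3)
        cs_b, report = rm.equate_forms(bank_a, form_b)
        joint = rm.als_decompose(form_b.to_pseudologit()[0], 3, seed=4,
                                 tol=1e-12, max_iter=300)
        assert np.nanmax(np.abs(cs_b.estimates - joint.estimates)) < 1e-5

    def test_common_item_fit_is_exact_without_noise(self, forms):
        dm, form_a, form_b = forms
        bank_a, _, _ = _bank_from(form_a, 3)
        _, report = rm.equate_forms(bank_a, form_b)
        assert report.overall_rmse < 1e-8
        assert report.equated

    def test_no_common_items_errors(self, forms):
        dm, form_a, _ = forms
        bank_a, _, _ = _bank_from(form_a, 3)
        disjoint = _split_form(dm, list(range(40, 60)))
        with pytest.raises(EquatingError):
            rm.equate_forms(bank_a, disjoint)

    def test_transitive_equating(self, forms):
        """Equating C -> B -> A equals equating C -> A directly (zero noise)."""
        dm, form_a, form_b = forms
        form_c = _split_form(dm, list(range(35, 60)) + list(range(10)))
        bank_a, _, _ = _bank_from(form_a, 3)
        # direct: C against A
        cs_direct, _ = rm.equate_forms(bank_a, form_c)
        # chained: B against A, build bank B, then C against B
        cs_b, rep_b = rm.equate_forms(bank_a, form_b)
        nm_b = rm.ResidualErrorModel(seed=2).fit(
            np.column_stack([rm.to_pseudologit(form_b.values[:, j],
                                               rep_b.fitted_metrics[cid])[0]
                             for j, cid in enumerate(form_b.col_ids)]),
            cs_b.estimates, 3).noise_model_
        tr = ScaleTransform(1.0, 0.0, 10.0, 50.0, fitted=True)
        bank_b = rm.build_item_bank(cs_b, nm_b, rep_b.fitted_metrics, np.ones(3), tr)
        cs_chained, _ = rm.equate_forms(bank_b, form_c)
        assert np.nanmax(np.abs(cs_chained.estimates - cs_direct.estimates)) < 1e-5


class TestItemDrift:
    def test_identical_coordinates(self):
        c = np.random.default_rng(0).standard_normal((3, 12))
        ids = [f"i{k}" for k in range(12)]
        report = rm.item_drift(c, c, ids)
        assert report.pooled == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in report.per_item.values())

    def test_disjoint_person_samples_reproduce_items(self, rank4_complete):
        """Specific objectivity: item coordinates replicate across samples."""
        dm, _ = rank4_complete
        half1 = rm.DataMatrix(dm.values[:75], dm.row_ids[:75], dm.col_ids)
        half2 = rm.DataMatrix(dm.values[75:], dm.row_ids[75:], dm.col_ids)
        c1 = rm.als_decompose(half1, 4, seed=1, tol=1e-12, max_iter=300).C
        c2 = rm.als_decompose(half2, 4, seed=8, tol=1e-12, max_iter=300).C
        report = rm.item_drift(c1, c2, dm.col_ids, align=True)
        assert report.pooled > 0.99

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(1)
        ids = [f"i{k}" for k in range(200)]
        report = rm.item_drift(rng.standard_normal((3, 200)),
                               rng.standard_normal((3, 200)), ids)
        assert abs(report.pooled) < 0.1

    def test_no_shared_items(self):
        with pytest.raises(EquatingError):
            rm.item_drift(np.ones((2, 2)), np.ones((2, 2)), [])


class TestItemBank:
    def test_round_trip(self, fitted_model):
        bank = fitted_model.bank_
        clone = rm.ItemBank.from_json(bank.to_json())
        assert clone.dimensionality == bank.dimensionality
        assert clone.cut_scores == bank.cut_scores
        assert set(clone.items) == set(bank.items)
        iid = next(iter(bank.items))
        assert np.allclose(clone.items[iid]["coords"], bank.items[iid]["coords"])
        name = next(iter(bank.constructs))
        assert np.allclose(clone.constructs[name]["coords"],
                           bank.constructs[name]["coords"])
        assert clone.constructs[name]["transform"].to_dict() == \
            bank.constructs[name]["transform"].to_dict()

    def test_bank_dimensionality_matches_calibration(self, fitted_model):
        assert fitted_model.bank_.dimensionality == fitted_model.d_

    def test_inconsistent_dimensionality_rejected(self):
        with pytest.raises(AssemblyError):
            rm.ItemBank(dimensionality=3, items={
                "a": {"coords": np.zeros(2), "metric": None,
                      "ear_coords": np.zeros(2), "ear_polyfit": np.zeros(2),
                      "se_coords": np.zeros(2), "se_polyfit": np.zeros(2)}})

    def test_cut_scores_must_increase(self):
        with pytest.raises(AssemblyError):
            rm.ItemBank(dimensionality=2, items={}, cut_scores=(50, 45, 55))
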