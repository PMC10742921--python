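"""End-to-end calibration: raw matrix -> item bank -> person scores.

`RiskScaleModel` chains the pieces the way a calibration run uses them:
pseudo-logit conversion, age-anchored factorization (optionally with an
objectivity search for the residual dimensionality), the residual error
model, construct coordinates regressed from ratings, the semi-true /
affine scale transform, and item-bank assembly.  `predict` scores new
persons straight from the fitted bank.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np

from .anchoring import age_anchored_calibration, age_regression, build_item_bank
from .datamatrix import DataMatrix
from .dimensionality import DimensionalitySelector
from .errors import DEFAULT_MISFIT_THRESHOLD, ResidualErrorModel, misfit
from .exceptions import DimensionMismatchError
from .metrics import ColumnMetric, to_pseudologit
from .scoring import (
    DEFAULT_CUT_SCORES,
    classify,
    construct_coordinates,
    drs_from_estimates,
    propagate_construct_se,
    score_person,
)

logger = logging.getLogger(__name__)


class RiskScaleModel:
    """Calibrate a screening scale and score persons from its item bank.

    Parameters
    ----------
    d_residual : int or "auto"
        Residual (non-age) dimensionality; "auto" runs the objectivity
        search on the age-residualized matrix.
    seed : int
        Master seed; stage sub-seeds are spawned from it.
    rating_categories : int
        Number of ordered construct-rating categories (default 11, a
        0-10 scale).
    cut_scores : tuple
        Reporting-scale category boundaries.
    misfit_threshold : float
        Person outfit above this flags the score uninterpretable.

    Attributes (after fit)
    ----------------------
    coords_, noise_, bank_ : calibration artifacts.
    construct_coords_, transform_ : scale construction.
    drs_, se_drs_, outfit_, interpretable_, categories_ : per-person results.
    best_d_report_ : dimensionality report when d_residual="auto".
    """

    def __init__(self, d_residual: Union[int, str] = 5, seed: int = 0,
                 rating_categories: int = 11,
                 cut_scores: tuple = DEFAULT_CUT_SCORES,
                 misfit_threshold: float = DEFAULT_MISFIT_THRESHOLD,
                 tol: float = 1e-6, max_iter: int = 200,
                 d_max: int = 10, n_seeds: int = 5,
                 pseudo_missing_fraction: float = 0.10):
        self.d_residual = d_residual
        self.seed = seed
        self.rating_categories = rating_categories
        self.cut_scores = cut_scores
        self.misfit_threshold = misfit_threshold
        self.tol = tol
        self.max_iter = max_iter
        self.d_max = d_max
        self.n_seeds = n_seeds
        self.pseudo_missing_fraction = pseudo_missing_fraction

    def get_params(self, deep=True) -> dict:
        return {k: getattr(self, k) for k in (
            "d_residual", "seed", "rating_categories", "cut_scores",
            "misfit_threshold", "tol", "max_iter", "d_max", "n_seeds",
            "pseudo_missing_fraction")}

    def set_params(self, **params) -> "RiskScaleModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------ fit

    def fit(self, X: DataMatrix, ages, ratings) -> "RiskScaleModel":
        if not isinstance(X, DataMatrix):
            raise DimensionMismatchError("X must be a DataMatrix with column metrics")
        sub = np.random.SeedSequence(self.seed).generate_state(3) % (2**31)
        x_pl, fitted_metrics = X.to_pseudologit()

        ratings = np.asarray(ratings, dtype=float)
        rating_metric = ColumnMetric("polytomous", self.rating_categories)
        ratings_pl, self.rating_metric_ = to_pseudologit(ratings, rating_metric)

        d_res = self.d_residual
        self.best_d_report_ = None
        if d_res == "auto":
            _, _, res = age_regression(x_pl, ages)
            sel = DimensionalitySelector(
                d_max=self.d_max, n_seeds=self.n_seeds,
                fraction=self.pseudo_missing_fraction, seed=int(sub[0]),
                tol=self.tol, max_iter=self.max_iter,
            ).fit(res)
            self.best_d_report_ = sel.report_
            d_res = sel.best_d_
            logger.info("objectivity search selected residual dimensionality %d", d_res)
        d_res = int(d_res)

        coords = age_anchored_calibration(
            x_pl, ages, d_res, seed=int(sub[1]), tol=self.tol, max_iter=self.max_iter,
        )
        e = coords.estimates
        d = coords.dimensionality

        err = ResidualErrorModel(seed=int(sub[2]), tol=self.tol,
                                 max_iter=self.max_iter).fit(x_pl, e, d)
        noise = err.noise_model_

        w, self.construct_fit_ = construct_coordinates(coords.R, ratings_pl)
        estimates = coords.R @ w

        mask = x_pl.mask
        construct_ses = np.empty(len(X.row_ids))
        for n in range(mask.shape[0]):
            obs = mask[n] & np.all(np.isfinite(coords.C), axis=0)
            ses = noise.se[n, obs]
            construct_ses[n] = (propagate_construct_se(ses, coords.C[:, obs], w)
                                if obs.sum() > d else np.inf)

        finite = np.isfinite(construct_ses)
        drs, transform = drs_from_estimates(
            estimates, np.where(finite, construct_ses, 0.0), "fit")

        fit_report = misfit(x_pl, e, noise.ear, threshold=self.misfit_threshold)

        self.coords_ = coords
        self.noise_ = noise
        self.d_ = d
        self.metrics_ = fitted_metrics
        self.construct_coords_ = w
        self.transform_ = transform
        self.drs_ = drs
        self.se_drs_ = transform.drs_per_logit * construct_ses
        self.outfit_ = fit_report.person_outfit
        self.item_outfit_ = fit_report.item_outfit
        self.interpretable_ = fit_report.person_interpretable
        self.categories_ = np.asarray(classify(drs, self.cut_scores))
        self.misfit_report_ = fit_report
        self.bank_ = build_item_bank(
            coords, noise, fitted_metrics, w, transform,
            cut_scores=self.cut_scores, seed=self.seed,
        )
        return self

    # -------------------------------------------------------------- scoring

    def score_person(self, responses: dict, **kwargs):
        if not hasattr(self, "bank_"):
            raise RuntimeError("score_person called before fit")
        kwargs.setdefault("misfit_threshold", self.misfit_threshold)
        return score_person(responses, self.bank_, **kwargs)

    def predict(self, X) -> np.ndarray:
        """Reporting-scale scores for new persons.

        ``X`` is a DataMatrix (columns matched against the bank by id) or
        a list of {item_id: value} dicts.
        """
        records = self._as_records(X)
        return np.asarray([self.score_person(rec).drs for rec in records])

    def predict_scores(self, X) -> list:
        """Full PersonScore objects instead of bare measures."""
        return [self.score_person(rec) for rec in self._as_records(X)]

    @staticmethod
    def _as_records(X) -> list:
        if isinstance(X, DataMatrix):
            out = []
            for n in range(X.shape[0]):
                row = X.values[n]
                out.append({cid: row[j] for j, cid in enumerate(X.col_ids)
                            if np.isfinite(row[j])})
            return out
        return list(X)

    # ------------------------------------------------------------ reporting

    def quality_report(self, labels=None, cut: Optional[float] = None):
        """Headline quality statistics for the calibration sample."""
        from .evaluate import QualityReport, binned_score_entropy, reliability_stats, roc_metrics

        finite = np.isfinite(self.se_drs_)
        rmse, separation, reliability = reliability_stats(
            self.drs_[finite], self.se_drs_[finite])
        bin_width = float(np.median(self.se_drs_[finite])) if finite.any() else 1.0
        n_bins, entropy, _ = binned_score_entropy(self.drs_[finite], bin_width)
        roc = None
        if labels is not None:
            roc = roc_metrics(self.drs_, labels,
                              cut if cut is not None else self.cut_scores[1])
        obs_items = np.isfinite(self.item_outfit_)
        return QualityReport(
            rmse=rmse, separation=separation, reliability=reliability,
            mean_item_outfit=float(np.mean(self.item_outfit_[obs_items])),
            entropy_bits=entropy, n_bins=n_bins,
            auc=roc["auc"] if roc else None,
            sensitivity=roc["sensitivity"] if roc else None,
            specificity=roc["specificity"] if roc else None,
        )
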