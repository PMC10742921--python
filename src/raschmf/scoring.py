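"""Construct coordinates, the 0-100 risk scale (DRS) and person scoring.

The construct (clinician) rating is regressed on the person coordinates
R; the regression coefficients are the *construct coordinates* and the
dot product R_n . w is a preliminary construct measure for person n.
Measures are rescaled to "semi-true" logits (a variance-restoring
rescale compensating for least-squares shrinkage) and then mapped by a
fixed affine transform onto a linear 0-100 scale whose calibration 1st
and 99th percentiles land at 10 and 90.

Scoring a new person needs only their responses and the item bank: the
banked item coordinates recover the person's position in the common
space, the banked EAR coordinates standardize their residuals into an
outfit statistic, and the banked observation counts feed the standard
error formula.  Examinee age is not required — the age dimension is
inferred from the responses themselves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .als import solve_coordinates
from .anchoring import ItemBank
from .errors import EPS_FLOOR, DEFAULT_MISFIT_THRESHOLD
from .exceptions import (
    DegenerateColumnError,
    DimensionMismatchError,
    InsufficientDataError,
    UncalibratedMetricError,
)
from .metrics import semi_true_logits, to_pseudologit

logger = logging.getLogger(__name__)

CATEGORIES = ("None", "Low", "Moderate", "Severe")
DEFAULT_CUT_SCORES = (45.0, 50.0, 55.0)


@dataclass
class ScaleTransform:
    """Affine map from semi-true construct logits to the reporting scale.

    ``semi_true_factor`` (g) and ``mean`` reproduce the variance-restoring
    rescale fitted at calibration; ``slope`` (> 0) and ``intercept`` place
    the result on the 0-100 scale.
    """

    semi_true_factor: float = 1.0
    mean: float = 0.0
    slope: float = 1.0
    intercept: float = 0.0
    fitted: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DimensionMismatchError("scale slope must be positive")

    def apply(self, estimates) -> np.ndarray:
        if not self.fitted:
            raise UncalibratedMetricError("scale transform has not been fitted")
        x = np.asarray(estimates, dtype=float)
        st = self.semi_true_factor * (x - self.mean) + self.mean
        return self.slope * st + self.intercept

    @property
    def drs_per_logit(self) -> float:
        """Combined slope of the full pseudo-logit -> scale map."""
        return self.slope * self.semi_true_factor

    def to_dict(self) -> dict:
        return {
            "semi_true_factor": self.semi_true_factor,
            "mean": self.mean,
            "slope": self.slope,
            "intercept": self.intercept,
            "fitted": self.fitted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleTransform":
        return cls(**{k: d[k] for k in
                      ("semi_true_factor", "mean", "slope", "intercept", "fitted")})


def construct_coordinates(R: np.ndarray, ratings: np.ndarray):
    """Regress normalized construct ratings on the person coordinates.

    Missing ratings are skipped; more rated persons than dimensions are
    required.  Returns (coords, fit_stats) where fit_stats carries the
    residual RMS of the predictions and the rated-person count.
    """
    R = np.asarray(R, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if y.shape[0] != R.shape[0]:
        raise DimensionMismatchError("ratings must align with R rows")
    obs = np.isfinite(y) & np.all(np.isfinite(R), axis=1)
    d = R.shape[1]
    if obs.sum() <= d:
        raise InsufficientDataError(
            f"{int(obs.sum())} rated persons cannot determine {d} coordinates"
        )
    w = solve_coordinates(y[obs], R[obs])
    resid = y[obs] - R[obs] @ w
    stats = {"rmse": float(np.sqrt(np.mean(resid**2))), "n_rated": int(obs.sum())}
    return w, stats


def fit_scale_transform(construct_estimates, person_ses, *,
                        anchor_percentiles=(1.0, 99.0),
                        anchor_scores=(10.0, 90.0)) -> ScaleTransform:
    """Fit the semi-true rescale plus the percentile-anchored affine map.

    The calibration sample's 1st/99th percentile semi-true logits map to
    scale scores 10/90 — robust to tail outliers while keeping scores
    inside [0, 100] without hard clipping.
    """
    x = np.asarray(construct_estimates, dtype=float)
    if x.size < 10:
        raise InsufficientDataError("need >= 10 persons to fit the scale transform")
    st, g = semi_true_logits(x, person_ses)
    p_lo, p_hi = np.percentile(st, anchor_percentiles)
    if p_hi <= p_lo:
        raise DegenerateColumnError("degenerate percentile anchors")
    s_lo, s_hi = anchor_scores
    slope = (s_hi - s_lo) / (p_hi - p_lo)
    intercept = s_lo - slope * p_lo
    return ScaleTransform(semi_true_factor=g, mean=float(np.mean(x)),
                          slope=float(slope), intercept=float(intercept), fitted=True)


def drs_from_estimates(construct_estimates, person_ses=None, transform="fit"):
    """Map construct estimates to the reporting scale.

    ``transform="fit"`` fits (and returns) a new :class:`ScaleTransform`
    from the calibration sample; otherwise the supplied transform is
    applied unchanged.  Returns (scores, transform).
    """
    x = np.asarray(construct_estimates, dtype=float)
    if isinstance(transform, str) and transform == "fit":
        if person_ses is None:
            person_ses = np.zeros_like(x)
        tr = fit_scale_transform(x, person_ses)
    else:
        tr = transform
        if not isinstance(tr, ScaleTransform) or not tr.fitted:
            raise UncalibratedMetricError("transform must be a fitted ScaleTransform")
    return tr.apply(x), tr


def classify(drs, cut_scores=DEFAULT_CUT_SCORES):
    """Risk category from half-open intervals [lower, upper).

    With the default cuts (45, 50, 55): below 45 -> None, [45, 50) ->
    Low, [50, 55) -> Moderate, 55 and above -> Severe.  Out-of-range
    scores clamp to the extreme categories.
    """
    cuts = np.asarray(cut_scores, dtype=float)
    if np.any(np.diff(cuts) <= 0) or cuts.size != len(CATEGORIES) - 1:
        raise DimensionMismatchError("cut scores must be strictly increasing, one per boundary")
    idx = np.searchsorted(cuts, np.asarray(drs, dtype=float), side="right")
    if np.ndim(drs) == 0:
        return CATEGORIES[int(idx)]
    return [CATEGORIES[k] for k in np.atleast_1d(idx)]


@dataclass
class PersonScore:
    """One scored person: measure, uncertainty, fit and classification."""

    drs: float
    se_drs: float
    outfit: float
    category: str
    interpretable: bool
    n_items_used: int

    def to_dict(self) -> dict:
        return {
            "drs": self.drs,
            "se": self.se_drs,
            "outfit": self.outfit,
            "category": self.category,
            "interpretable": self.interpretable,
            "n_items_used": self.n_items_used,
        }


def _person_ear(res: np.ndarray, ear_col_coords: np.ndarray,
                ear_polyfit: np.ndarray, mean_ears: np.ndarray) -> np.ndarray:
    """Per-response EAR from banked error coordinates.

    The person's 2-dimensional error coordinates are solved from their
    log squared residuals against the banked item error coordinates, then
    pushed back through each item's polyfit.  Fitted squares are floored
    at 1% of the item's mean calibration EAR squared, mirroring the
    calibration-side guard against near-zero predictions.
    """
    logsq = np.log(np.maximum(res**2, EPS_FLOOR))
    u, *_ = np.linalg.lstsq(ear_col_coords.T, logsq, rcond=None)
    log_hat = np.clip(ear_col_coords.T @ u, -60.0, 60.0)
    fitted = ear_polyfit[:, 0] * np.exp(log_hat) + ear_polyfit[:, 1]
    floors = np.maximum(0.01 * np.nan_to_num(mean_ears) ** 2, EPS_FLOOR)
    return np.sqrt(np.maximum(fitted, floors))


def propagate_construct_se(item_ses: np.ndarray, item_coords: np.ndarray,
                           construct_coords: np.ndarray) -> float:
    """Standard error of w . R_n through the least-squares covariance.

    With R_n = (A A^T)^{-1} A x (A the D x m matrix of matched item
    coordinates) and independent cell errors se_i,

        Var(w . R_n) = w^T P diag(se^2) P^T w,  P = (A A^T)^{-1} A.
    """
    a = np.asarray(item_coords, dtype=float)
    p = np.linalg.solve(a @ a.T, a)
    pw = p.T @ np.asarray(construct_coords, dtype=float)
    finite = np.isfinite(item_ses)
    if not finite.all():
        return float("inf")
    return float(np.sqrt(np.sum((pw * item_ses) ** 2)))


def score_person(responses: dict, bank: ItemBank, *, construct_id=None,
                 min_items=None,
                 misfit_threshold: float = DEFAULT_MISFIT_THRESHOLD) -> PersonScore:
    """Score one person from raw responses and a calibrated item bank.

    ``responses`` maps item id to raw value.  Unknown ids are skipped
    with a warning; fewer matched items than the floor (default 2D)
    raises :class:`InsufficientDataError`.
    """
    d = bank.dimensionality
    floor = int(min_items) if min_items is not None else 2 * d
    floor = max(floor, d + 1)

    known = [i for i in responses if str(i) in bank.items]
    unknown = [i for i in responses if str(i) not in bank.items]
    if unknown:
        warnings.warn(f"unknown item ids skipped: {sorted(map(str, unknown))[:10]}")
    matched, x_pl = [], []
    for iid in known:
        rec = bank.items[str(iid)]
        val, _ = to_pseudologit(np.asarray([responses[iid]], float), rec["metric"])
        if np.isfinite(val[0]):
            matched.append(str(iid))
            x_pl.append(val[0])
    m = len(matched)
    if m < floor:
        raise InsufficientDataError(
            f"{m} matched responses below the scoring floor of {floor} (D={d})"
        )
    x = np.asarray(x_pl)
    a = bank.coords_matrix(matched)                       # D x m
    r_n = solve_coordinates(x, a.T)
    res = x - a.T @ r_n

    ear_cc = np.column_stack([bank.items[i]["ear_coords"] for i in matched])
    ear_pf = np.vstack([bank.items[i]["ear_polyfit"] for i in matched])
    mean_ears = np.asarray([bank.items[i].get("mean_ear", np.nan) for i in matched])
    ear = _person_ear(res, ear_cc, ear_pf, mean_ears)
    outfit = float(np.sqrt(np.mean((res / ear) ** 2)))

    from .errors import standard_error  # local import keeps module load light

    c_counts = np.asarray([bank.items[i]["n_obs"] for i in matched], float)
    item_ses = standard_error(ear, np.full(m, float(m)), c_counts, d)

    if construct_id is None:
        construct_id = next(iter(bank.constructs))
    construct = bank.constructs[construct_id]
    w = np.asarray(construct["coords"], dtype=float)
    tr: ScaleTransform = construct["transform"]
    measure = float(w @ r_n)
    drs = float(tr.apply(measure))
    se_construct = propagate_construct_se(item_ses, a, w)
    se_drs = float(tr.drs_per_logit * se_construct)

    return PersonScore(
        drs=drs,
        se_drs=se_drs,
        outfit=outfit,
        category=classify(drs, bank.cut_scores),
        interpretable=bool(outfit < misfit_threshold),
        n_items_used=m,
    )
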