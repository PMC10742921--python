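"""Residual decomposition: EAR, cell standard errors, ESE and misfit.

Three levels of error are distinguished.  Raw residuals Res = X - E are
the observed discrepancies.  The *expected absolute residual* EAR models
the characteristic residual scale per cell by decomposing the log squared
residuals at dimensionality 2 (the log turns the multiplicative
row-by-column noise model into an additive one, hence the extra
dimension) and mapping back through a per-column degree-1 polynomial fit.
The *standard error* SE estimates the distance between an estimate and
the unobservable true value:

    SE = 2 * EAR * sqrt(d) / ((r - d) * (c - d))^(1/4)

where r and c count the observed cells in the row and column and d is the
dimensionality.  When r = d or c = d the decomposition can reproduce any
observation exactly, so the standard error diverges to infinity.  The
*expected standard error* ESE smooths SE by the same log-decomposition
pipeline, yielding portable 2-dimensional error coordinates per person
and item.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .als import ALSFactorization
from .datamatrix import DataMatrix
from .exceptions import DimensionMismatchError

logger = logging.getLogger(__name__)

#: floor applied to squared residuals before taking logs
EPS_FLOOR = 1e-12
#: clip on log-scale estimates before exponentiation (overflow guard)
_LOG_CLIP = 60.0
DEFAULT_MISFIT_THRESHOLD = 2.0


def residuals(X, E: np.ndarray) -> np.ndarray:
    """Signed residuals X - E on observed cells, NaN elsewhere."""
    x = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    e = np.asarray(E, dtype=float)
    if x.shape != e.shape:
        raise DimensionMismatchError("X and E shapes differ")
    return np.where(np.isfinite(x), x - e, np.nan)


def _log_square_decompose(values: np.ndarray, seed: int, tol: float,
                          max_iter: int):
    """Shared pipeline for EAR (Eq.-style) and ESE estimation.

    squares -> floor -> log -> 2-dim ALS -> exp -> per-column degree-1
    polyfit against the raw squares -> floor -> sqrt.

    ``values`` holds the quantities to square (residuals or SEs) with NaN
    at cells excluded from the fit.  Returns (matrix, row_coords,
    col_coords, polyfit_coefs) where polyfit_coefs is I x 2 (slope,
    intercept per column).

    The degree-1 fit can dip below zero for cells with small estimates;
    fitted squares are floored at 1% of the column's observed mean
    squared value (and at EPS_FLOOR absolutely), so the returned scale
    never drops below 10% of the column RMS — a pure-floor of EPS would
    otherwise turn a near-zero prediction into an astronomical misfit.
    """
    mask = np.isfinite(values)
    sq = np.where(mask, values**2, np.nan)
    sq = np.where(mask, np.maximum(sq, EPS_FLOOR), np.nan)
    logsq = np.log(sq)

    from .exceptions import DegenerateSpaceError

    try:
        est = ALSFactorization(n_dims=2, seed=seed, tol=tol, max_iter=max_iter).fit(logsq)
        row_coords, col_coords = est.R_, est.C_
        log_hat = est.E_
    except DegenerateSpaceError:
        # exact-fit (or otherwise constant) residuals: the log matrix has
        # no 2-dimensional structure; fall back to per-row/column means
        logger.warning("degenerate residual structure; using additive mean model")
        row_mean = np.nanmean(logsq, axis=1)
        col_dev = np.nanmean(logsq - row_mean[:, None], axis=0)
        row_coords = np.column_stack([row_mean, np.ones_like(row_mean)])
        col_coords = np.vstack([np.ones_like(col_dev), col_dev])
        log_hat = row_coords @ col_coords
    log_hat = np.clip(log_hat, -_LOG_CLIP, _LOG_CLIP)
    h = np.exp(log_hat)

    n, i = values.shape
    coefs = np.ones((i, 2))
    coefs[:, 1] = 0.0
    fitted = np.array(h)
    floors = np.full(i, EPS_FLOOR)
    for j in range(i):
        obs = mask[:, j] & np.isfinite(h[:, j])
        if obs.any():
            floors[j] = max(EPS_FLOOR, 0.01 * float(np.mean(sq[obs, j])))
        if obs.sum() >= 3 and np.nanstd(h[obs, j]) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                slope, intercept = np.polyfit(h[obs, j], sq[obs, j], 1)
            coefs[j] = (slope, intercept)
            fitted[:, j] = slope * h[:, j] + intercept
    out = np.sqrt(np.maximum(fitted, floors[None, :]))
    return out, row_coords, col_coords, coefs


def estimate_ear(res: np.ndarray, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 50):
    """Expected absolute residuals plus their 2-dimensional coordinates.

    Returns (ear, (row_coords, col_coords), polyfit_coefs).  EAR is
    defined on every cell (missing cells are filled from the
    coordinates); exact-fit data floors at sqrt(EPS_FLOOR).
    """
    res = np.asarray(res, dtype=float)
    return_tuple = _log_square_decompose(res, seed, tol, max_iter)
    ear, rc, cc, coefs = return_tuple
    return ear, (rc, cc), coefs


def standard_error(ear, r, c, d, formula: str = "canonical"):
    """Cell standard error from EAR, observation counts and dimensionality.

    ``formula="canonical"`` uses (r - d)(c - d) in the denominator (the
    variant whose divergence matches the r = d / c = d argument);
    ``formula="legacy"`` uses (r - 1)(c - 1).  Scalar or array inputs.
    """
    ear = np.asarray(ear, dtype=float)
    r = np.asarray(r, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(r < d) or np.any(c < d):
        raise DimensionMismatchError("observation counts below dimensionality")
    if formula == "canonical":
        denom4 = (r - d) * (c - d)
    elif formula == "legacy":
        denom4 = (r - 1.0) * (c - 1.0)
    else:
        raise ValueError(f"unknown formula {formula!r}")
    with np.errstate(divide="ignore"):
        out = 2.0 * ear * np.sqrt(d) / np.power(denom4, 0.25)
        out = np.where(denom4 <= 0, np.inf, out)
    if out.ndim == 0:
        return float(out)
    return out


def one_facet_se(ear, n):
    """One-facet, one-dimension reduction of the SE formula: ear / sqrt(n - 1)."""
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.asarray(ear, dtype=float) / np.sqrt(n - 1.0)
        out = np.where(n <= 1, np.inf, out)
    return float(out) if out.ndim == 0 else out


def se_matrix(ear: np.ndarray, mask: np.ndarray, d: int,
              formula: str = "canonical") -> np.ndarray:
    """Cell SE over the whole matrix using observed row/column counts."""
    r = mask.sum(axis=1).astype(float)[:, None]
    c = mask.sum(axis=0).astype(float)[None, :]
    return standard_error(ear, np.broadcast_to(r, ear.shape),
                          np.broadcast_to(c, ear.shape), d, formula=formula)


def estimate_ese(se: np.ndarray, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 50):
    """Expected standard errors: the EAR pipeline applied to the SE matrix.

    Infinite SE cells are excluded from the fit and refilled from the
    2-dimensional coordinates, which are what an item bank persists.
    """
    se = np.asarray(se, dtype=float)
    work = np.where(np.isfinite(se), se, np.nan)
    ese, rc, cc, coefs = _log_square_decompose(work, seed, tol, max_iter)
    return ese, (rc, cc), coefs


@dataclass
class MisfitReport:
    """Cell misfit with person/item outfit summaries."""

    cell: np.ndarray
    person_outfit: np.ndarray
    item_outfit: np.ndarray
    person_interpretable: np.ndarray
    frac_large: float
    threshold: float


def misfit(X, E: np.ndarray, ear: np.ndarray,
           threshold: float = DEFAULT_MISFIT_THRESHOLD) -> MisfitReport:
    """Residuals standardized by EAR; outfit = RMS misfit per person/item.

    A person is *interpretable* when their outfit stays below the
    threshold (default 2.0); ``frac_large`` reports the share of observed
    cells with |misfit| above the threshold.
    """
    res = residuals(X, E)
    cell = res / np.asarray(ear, dtype=float)
    with np.errstate(invalid="ignore"):
        person = np.sqrt(np.nanmean(cell**2, axis=1))
        item = np.sqrt(np.nanmean(cell**2, axis=0))
    obs = np.isfinite(cell)
    frac = float(np.mean(np.abs(cell[obs]) > threshold)) if obs.any() else 0.0
    return MisfitReport(
        cell=cell,
        person_outfit=person,
        item_outfit=item,
        person_interpretable=person < threshold,
        frac_large=frac,
        threshold=threshold,
    )


@dataclass
class NoiseModel:
    """Residual/EAR/SE/ESE matrices and their portable coordinates."""

    residuals: np.ndarray
    ear: np.ndarray
    se: np.ndarray
    ese: np.ndarray
    ear_row_coords: np.ndarray
    ear_col_coords: np.ndarray
    ear_polyfit: np.ndarray
    se_row_coords: np.ndarray
    se_col_coords: np.ndarray
    se_polyfit: np.ndarray
    row_counts: np.ndarray
    col_counts: np.ndarray
    d: int


class ResidualErrorModel:
    """Estimator computing the full noise model from (X, E).

    Attributes after :meth:`fit`: ``residuals_``, ``ear_``, ``se_``,
    ``ese_``, coordinate pairs for EAR and SE, ``noise_model_``.
    """

    def __init__(self, seed: int = 0, tol: float = 1e-6, max_iter: int = 50,
                 formula: str = "canonical"):
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.formula = formula

    def get_params(self, deep=True) -> dict:
        return {k: getattr(self, k) for k in ("seed", "tol", "max_iter", "formula")}

    def set_params(self, **params) -> "ResidualErrorModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, E: np.ndarray, d: int) -> "ResidualErrorModel":
        x = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
        mask = np.isfinite(x)
        res = residuals(x, E)
        sub_seeds = np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        ear, (ear_rc, ear_cc), ear_coefs = estimate_ear(
            res, seed=int(sub_seeds[0]), tol=self.tol, max_iter=self.max_iter)
        se = se_matrix(ear, mask, d, formula=self.formula)
        ese, (se_rc, se_cc), se_coefs = estimate_ese(
            se, seed=int(sub_seeds[1]), tol=self.tol, max_iter=self.max_iter)
        self.residuals_ = res
        self.ear_ = ear
        self.se_ = se
        self.ese_ = ese
        self.noise_model_ = NoiseModel(
            residuals=res, ear=ear, se=se, ese=ese,
            ear_row_coords=ear_rc, ear_col_coords=ear_cc, ear_polyfit=ear_coefs,
            se_row_coords=se_rc, se_col_coords=se_cc, se_polyfit=se_coefs,
            row_counts=mask.sum(axis=1), col_counts=mask.sum(axis=0), d=d,
        )
        return self
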