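"""Column metrics and the pseudo-logit common scale.

Alternating least squares needs every column of the response matrix on one
unbounded, approximately linear metric.  Raw columns, however, arrive as
dichotomous scores, polytomous ratings, interval measurements or
ratio-scaled timings.  Each column is therefore assigned a *plausible*
logit value per raw value ("pseudo-logit"):

- dichotomous 0/1     -> logit(0.25) / logit(0.75)
- polytomous k of K   -> logit((k + 0.5) / K)
- interval            -> column z-score
- ratio               -> z-score of the natural log (hard floor at zero
                         motivates the log)

All maps are strictly monotone in the raw value and invertible once the
fitted standardization parameters are stored on the :class:`ColumnMetric`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .exceptions import (
    DegenerateColumnError,
    DimensionMismatchError,
    MetricViolationError,
    UncalibratedMetricError,
)

#: probability clamp applied before any logit
_P_CLAMP = 1e-6

#: plausible success probabilities assigned to dichotomous 0/1 responses
DICHOTOMOUS_PROBS = (0.25, 0.75)

VALID_KINDS = ("dichotomous", "polytomous", "interval", "ratio")


@dataclass
class ColumnMetric:
    """Declared measurement level of one data column plus fitted parameters.

    Parameters
    ----------
    kind : str
        One of ``dichotomous``, ``polytomous``, ``interval``, ``ratio``.
    n_categories : int, optional
        Number of ordered categories (dichotomous implies 2).
    location, scale : float
        Standardization parameters recorded at calibration time so the
        transform can be replayed exactly on new persons and inverted.
    """

    kind: str = "interval"
    n_categories: Optional[int] = None
    location: float = 0.0
    scale: float = 1.0
    fitted: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise MetricViolationError(f"unknown metric kind {self.kind!r}")
        if self.kind == "dichotomous":
            if self.n_categories not in (None, 2):
                raise MetricViolationError("dichotomous metric implies 2 categories")
            self.n_categories = 2
        if self.kind == "polytomous" and (self.n_categories is None or self.n_categories < 2):
            raise MetricViolationError("polytomous metric needs n_categories >= 2")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise MetricViolationError("scale must be finite and positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_categories": self.n_categories,
            "location": float(self.location),
            "scale": float(self.scale),
            "fitted": bool(self.fitted),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMetric":
        return cls(
            kind=d["kind"],
            n_categories=d.get("n_categories"),
            location=float(d.get("location", 0.0)),
            scale=float(d.get("scale", 1.0)),
            fitted=bool(d.get("fitted", False)),
        )


def _safe_logit(p: np.ndarray) -> np.ndarray:
    return logit(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))


def to_pseudologit(column: np.ndarray, metric: ColumnMetric) -> tuple[np.ndarray, ColumnMetric]:
    """Map one raw column onto the pseudo-logit metric.

    Missing values (NaN) stay missing.  Returns the transformed column and
    a *fitted* copy of the metric carrying the parameters needed by
    :func:`from_pseudologit`.

    When ``metric.fitted`` is already True the stored parameters are
    replayed rather than re-estimated (used when scoring new persons
    against a calibrated bank).
    """
    x = np.asarray(column, dtype=float)
    obs = np.isfinite(x)
    out = np.full_like(x, np.nan)
    kind = metric.kind

    if kind == "dichotomous":
        vals = x[obs]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
            raise MetricViolationError("dichotomous column contains values outside {0, 1}")
        lo, hi = _safe_logit(np.array(DICHOTOMOUS_PROBS))
        out[obs] = np.where(vals > 0.5, hi, lo)
        fitted = ColumnMetric(kind, 2, 0.0, 1.0, fitted=True)
        return out, fitted

    if kind == "polytomous":
        k_cat = int(metric.n_categories)
        vals = x[obs]
        if vals.size:
            rounded = np.round(vals)
            if np.any(np.abs(vals - rounded) > 1e-9) or np.any(rounded < 0) or np.any(rounded >= k_cat):
                raise MetricViolationError(
                    f"polytomous column must hold integers in 0..{k_cat - 1}"
                )
            out[obs] = _safe_logit((rounded + 0.5) / k_cat)
        fitted = ColumnMetric(kind, k_cat, 0.0, 1.0, fitted=True)
        return out, fitted

    if kind == "ratio":
        vals = x[obs]
        if np.any(vals < 0):
            raise MetricViolationError("ratio column contains negative values")
        floor = np.min(vals[vals > 0]) / 2.0 if np.any(vals > 0) else 1e-9
        logged = np.log(np.maximum(vals, floor))
        work = logged
    else:  # interval
        work = x[obs]

    if metric.fitted:
        loc, scale = metric.location, metric.scale
    else:
        loc = float(np.mean(work)) if work.size else 0.0
        scale = float(np.std(work)) if work.size else 0.0
        if scale <= 0 or not np.isfinite(scale):
            raise DegenerateColumnError("zero-variance column cannot be standardized")
    out[obs] = (work - loc) / scale
    fitted = ColumnMetric(kind, metric.n_categories, loc, scale, fitted=True)
    return out, fitted


def from_pseudologit(column: np.ndarray, metric: ColumnMetric) -> np.ndarray:
    """Invert :func:`to_pseudologit`.

    Continuous kinds recover the raw values exactly; categorical kinds
    return the expected probability / category implied by the plausible
    value map (a pseudo-logit of 0 on a dichotomous column is probability
    0.5).
    """
    if not metric.fitted:
        raise UncalibratedMetricError("metric has no fitted parameters")
    z = np.asarray(column, dtype=float)
    if metric.kind == "dichotomous":
        return expit(z)
    if metric.kind == "polytomous":
        return expit(z) * metric.n_categories - 0.5
    raw = z * metric.scale + metric.location
    if metric.kind == "ratio":
        return np.exp(raw)
    return raw


def semi_true_logits(
    estimates: np.ndarray, person_ses: np.ndarray
) -> tuple[np.ndarray, float]:
    """Variance-restoring rescale of construct estimates.

    Least-squares estimates are shrunk relative to the latent values by
    measurement noise; the rescale re-inflates their spread using the
    average measurement error of the sample:

        g = sqrt(1 + RMSE^2 / var(estimates)),  RMSE = sqrt(mean(se^2))
        out = g * (x - mean(x)) + mean(x)

    Returns the rescaled vector and the factor ``g`` for persistence.
    """
    x = np.asarray(estimates, dtype=float)
    se = np.asarray(person_ses, dtype=float)
    if x.shape != se.shape:
        raise DimensionMismatchError("estimates and ses must have equal length")
    if np.any(se < 0):
        raise MetricViolationError("standard errors must be non-negative")
    var = float(np.var(x))
    if var <= 0:
        raise DegenerateColumnError("zero-variance estimates: rescale factor undefined")
    finite = np.isfinite(se)
    if not np.all(finite):
        warnings.warn("infinite standard errors ignored in semi-true rescale")
    rmse2 = float(np.mean(se[finite] ** 2)) if finite.any() else 0.0
    g = float(np.sqrt(1.0 + rmse2 / var))
    mean = float(np.mean(x))
    return g * (x - mean) + mean, g
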