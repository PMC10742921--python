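"""Scale-quality statistics: reliability, entropy, ROC.

Separation is the ratio of the error-disattenuated person spread to the
root-mean-square measurement error; reliability is its squared-ratio
normalization to [0, 1] (the Rasch analogue of Cronbach's alpha).
Entropy comparisons treat a continuous scale as informative in
standard-error-sized bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.metrics import auc, roc_curve

from .exceptions import DegenerateColumnError, DimensionMismatchError


def reliability_from_separation(separation: float) -> float:
    """separation^2 / (1 + separation^2)."""
    s = float(separation)
    if not np.isfinite(s):
        return 1.0
    return s**2 / (1.0 + s**2)


def reliability_stats(measures, ses):
    """(rmse, separation, reliability) for a sample of person measures.

    rmse = sqrt(mean(se^2)); true spread is the error-disattenuated
    sd, sd_true = sqrt(max(var(measures) - rmse^2, 0)); separation =
    sd_true / rmse.  rmse of zero yields reliability 1 with infinite
    separation (flagged by a warning).
    """
    x = np.asarray(measures, dtype=float)
    se = np.asarray(ses, dtype=float)
    if x.shape != se.shape:
        raise DimensionMismatchError("measures and ses must align")
    if x.size < 2:
        raise DimensionMismatchError("need at least 2 persons")
    if not np.all(np.isfinite(se)):
        raise DimensionMismatchError("standard errors must be finite")
    rmse = float(np.sqrt(np.mean(se**2)))
    if rmse == 0.0:
        warnings.warn("zero measurement error: separation is infinite")
        return 0.0, float("inf"), 1.0
    sd_true = float(np.sqrt(max(np.var(x) - rmse**2, 0.0)))
    separation = sd_true / rmse
    return rmse, separation, reliability_from_separation(separation)


def shannon_entropy(probabilities) -> float:
    """Base-2 Shannon entropy; 0 * log 0 is taken as 0."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise DimensionMismatchError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        warnings.warn(f"probabilities sum to {total:.6g}; renormalizing")
        if total <= 0:
            raise DegenerateColumnError("probabilities sum to zero")
        p = p / total
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def binned_score_entropy(measures, bin_width: float, value_range=None):
    """Entropy of a continuous scale partitioned into equal-width bins.

    Bin count is floor(range / width) over the observed (or supplied)
    range; returns (n_bins, empirical_entropy, equiprobable_entropy)
    where the equiprobable figure is log2(n_bins).  A degenerate range
    collapses to a single zero-entropy bin.
    """
    x = np.asarray(measures, dtype=float)
    if bin_width <= 0:
        raise DimensionMismatchError("bin width must be positive")
    lo, hi = (float(np.min(x)), float(np.max(x))) if value_range is None else map(float, value_range)
    n_bins = int(np.floor((hi - lo) / bin_width))
    if n_bins < 1:
        return 1, 0.0, 0.0
    idx = np.clip(((x - lo) / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    probs = counts / counts.sum()
    return n_bins, shannon_entropy(probs), float(np.log2(n_bins))


def roc_metrics(scores, binary_labels, cut: float):
    """AUC (trapezoidal over all thresholds) plus operating-point metrics.

    The operating point calls a case positive when score >= cut.
    Returns a dict with auc, sensitivity, specificity, accuracy and the
    ROC points (fpr, tpr arrays).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateColumnError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    area = float(auc(fpr, tpr))
    pred = (s >= cut).astype(int)
    pos, neg = y == 1, y == 0
    sensitivity = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    specificity = float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    accuracy = float(np.mean(pred == y))
    return {
        "auc": area,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": accuracy,
        "fpr": fpr,
        "tpr": tpr,
    }


@dataclass
class QualityReport:
    """Headline scale-quality numbers, serializable to JSON."""

    rmse: float
    separation: float
    reliability: float
    mean_item_outfit: float
    entropy_bits: float
    n_bins: int
    auc: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None

    def __post_init__(self) -> None:
        expected = reliability_from_separation(self.separation)
        if np.isfinite(self.separation) and abs(self.reliability - expected) > 1e-10:
            raise DimensionMismatchError("reliability inconsistent with separation")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rmse", "separation", "reliability", "mean_item_outfit",
            "entropy_bits", "n_bins", "auc", "sensitivity", "specificity")}
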