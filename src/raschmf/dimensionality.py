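"""Objectivity-driven dimensionality selection.

Three statistics are computed per candidate dimensionality d:

- *accuracy*: hide a seeded random subset of observed cells
  ("pseudo-missing"), refit, and correlate the hidden observations with
  their estimates — a cross-validated prediction score.
- *stability*: fit person coordinates R from two non-overlapping item
  halves (alternating columns), align the second solution to the first by
  orthogonal Procrustes rotation (independent runs differ by an arbitrary
  rotation of the space), and correlate corresponding entries.
- *objectivity*: sqrt(accuracy * stability).

Objectivity peaks at the true dimensionality: below it the model misses
signal (low accuracy), above it the model fits noise that does not
replicate across item samples (low stability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import pearsonr

from .als import ALSFactorization
from .datamatrix import DataMatrix
from .exceptions import InfeasibleHoldoutError, InfeasibleSplitError

DEFAULT_FRACTION = 0.10
DEFAULT_N_SEEDS = 5
DEFAULT_D_MAX = 10


def _as_array(X):
    return X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)


def _pseudo_missing_mask(mask: np.ndarray, d: int, fraction: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Select observed cells to hide, keeping > d observations per row/col."""
    rows, cols = np.where(mask)
    target = int(round(fraction * rows.size))
    if target < 2:
        raise InfeasibleHoldoutError("too few observed cells to hide a holdout set")
    order = rng.permutation(rows.size)
    row_counts = mask.sum(axis=1).astype(int)
    col_counts = mask.sum(axis=0).astype(int)
    hide = np.zeros_like(mask)
    n_hidden = 0
    for k in order:
        r, c = rows[k], cols[k]
        if row_counts[r] - 1 > d and col_counts[c] - 1 > d:
            hide[r, c] = True
            row_counts[r] -= 1
            col_counts[c] -= 1
            n_hidden += 1
            if n_hidden >= target:
                break
    if n_hidden < 2:
        raise InfeasibleHoldoutError("could not hide cells without starving rows/columns")
    return hide


def accuracy(X, d: int, fraction: float = DEFAULT_FRACTION, seed: int = 0,
             **als_options) -> float:
    """Correlation between pseudo-missing observations and their estimates."""
    x = _as_array(X)
    mask = np.isfinite(x)
    if not 0 < fraction <= 0.25:
        raise InfeasibleHoldoutError("pseudo-missing fraction must lie in (0, 0.25]")
    ss = np.random.SeedSequence(seed)
    hold_rng = np.random.default_rng(ss.spawn(1)[0])
    hide = _pseudo_missing_mask(mask, d, fraction, hold_rng)
    x_train = np.where(hide, np.nan, x)
    est = ALSFactorization(n_dims=d, seed=seed, **als_options).fit(x_train)
    e = est.E_[hide]
    obs = x[hide]
    ok = np.isfinite(e)
    if ok.sum() < 2:
        raise InfeasibleHoldoutError("no recoverable holdout estimates")
    r, _ = pearsonr(obs[ok], e[ok])
    return float(r)


def stability(X, d: int, seed: int = 0, **als_options) -> float:
    """Correlation of R computed from alternating item halves.

    The two independently calibrated R matrices live in arbitrarily
    rotated frames, so the second is aligned to the first by orthogonal
    Procrustes before correlating.
    """
    x = _as_array(X)
    i = x.shape[1]
    halves = (np.arange(0, i, 2), np.arange(1, i, 2))
    if min(h.size for h in halves) <= d:
        raise InfeasibleSplitError(f"an item half has <= {d} columns")
    sub_seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    coords = []
    for h, s in zip(halves, sub_seeds):
        est = ALSFactorization(n_dims=d, seed=int(s), **als_options).fit(x[:, h])
        coords.append(est.R_)
    r1, r2 = coords
    both = np.all(np.isfinite(r1), axis=1) & np.all(np.isfinite(r2), axis=1)
    if both.sum() <= d:
        raise InfeasibleSplitError("too few persons calibrated in both halves")
    rot, _ = orthogonal_procrustes(r2[both], r1[both])
    r, _ = pearsonr(r1[both].ravel(), (r2[both] @ rot).ravel())
    return float(r)


def objectivity(accuracy: float, stability: float) -> float:
    """Root product of accuracy and stability.

    Negative inputs are clamped to zero (with a warning): the square root
    of a negative product is undefined and a negative correlation carries
    no evidence of reproducible structure.
    """
    a, s = float(accuracy), float(stability)
    if a < 0 or s < 0:
        warnings.warn("negative accuracy/stability clamped to 0 before root product")
        a, s = max(a, 0.0), max(s, 0.0)
    return float(np.sqrt(a * s))


@dataclass
class DimensionalityReport:
    """Per-dimensionality accuracy/stability/objectivity records."""

    records: list  # of dicts {d, accuracy, stability, objectivity, best_seed}
    best_d: int
    pseudo_missing_fraction: float
    seeds_tried: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "best_d": int(self.best_d),
            "pseudo_missing_fraction": self.pseudo_missing_fraction,
            "seeds_tried": [int(s) for s in self.seeds_tried],
            "records": self.records,
        }


def select_best(records: list) -> int:
    """Argmax-objectivity dimensionality; exact ties go to the smallest d."""
    best = max(records, key=lambda rec: (rec["objectivity"], -rec["d"]))
    return int(best["d"])


class DimensionalitySelector:
    """Evaluate candidate dimensionalities and pick the objectivity peak.

    Each candidate d in 1..d_max is scored over ``n_seeds`` random
    initializations; the best seed per d (maximum objectivity) is kept,
    and the reported best dimensionality maximizes objectivity across d.
    """

    def __init__(self, d_max=DEFAULT_D_MAX, n_seeds=DEFAULT_N_SEEDS,
                 fraction=DEFAULT_FRACTION, seed=0, tol=1e-6, max_iter=50):
        self.d_max = d_max
        self.n_seeds = n_seeds
        self.fraction = fraction
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True) -> dict:
        return {k: getattr(self, k) for k in (
            "d_max", "n_seeds", "fraction", "seed", "tol", "max_iter")}

    def set_params(self, **params) -> "DimensionalitySelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X) -> "DimensionalitySelector":
        x = _as_array(X)
        n, i = x.shape
        if self.d_max >= min(n, i) / 2:
            raise InfeasibleSplitError("d_max must be below min(N, I) / 2")
        seeds = (np.random.SeedSequence(self.seed).generate_state(self.n_seeds)
                 % (2**31)).astype(int)
        als_opts = {"tol": self.tol, "max_iter": self.max_iter}
        records = []
        for d in range(1, self.d_max + 1):
            best = None
            for s in seeds:
                acc = accuracy(x, d, fraction=self.fraction, seed=int(s), **als_opts)
                stab = stability(x, d, seed=int(s), **als_opts)
                obj = objectivity(acc, stab)
                if best is None or obj > best["objectivity"]:
                    best = {"d": d, "accuracy": acc, "stability": stab,
                            "objectivity": obj, "best_seed": int(s)}
            records.append(best)
        self.report_ = DimensionalityReport(
            records=records,
            best_d=select_best(records),
            pseudo_missing_fraction=self.fraction,
            seeds_tried=list(seeds),
        )
        self.best_d_ = self.report_.best_d
        return self


def best_dimensionality(X, d_max: int = DEFAULT_D_MAX,
                        n_seeds: int = DEFAULT_N_SEEDS, *,
                        fraction: float = DEFAULT_FRACTION, seed: int = 0,
                        **als_options) -> DimensionalityReport:
    """Thin wrapper over :class:`DimensionalitySelector`."""
    sel = DimensionalitySelector(d_max=d_max, n_seeds=n_seeds,
                                 fraction=fraction, seed=seed, **als_options)
    return sel.fit(X).report_
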