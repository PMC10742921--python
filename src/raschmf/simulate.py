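"""Model-conforming synthetic data with known truth.

The generative schema is T = R_true C_true with D independent
dimensions, plus cell-wise Gaussian noise whose scale is the product of a
base level and lognormal per-row and per-column multipliers (each person
and item has a characteristic degree of noise).  The instrument variant
emulates the screening-study structure: ages spanning 7-82 with
standardized log-age as the first dimension, a constant "difficulty"
offset dimension, three overlapping age forms producing ~25% blocked
missingness, dichotomous item columns paired with negatively-loaded
ratio-scaled timing columns, and a 0-10 discrete construct rating driven
by a projection of the true person coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .datamatrix import DataMatrix
from .exceptions import DimensionMismatchError
from .metrics import ColumnMetric


@dataclass
class SimulationSpec:
    """Generator parameters; defaults mirror the study's shape at desk scale."""

    n_persons: int = 300
    n_items: int = 120
    true_d: int = 6
    noise_base: float = 1.0
    row_noise_spread: float = 0.3
    col_noise_spread: float = 0.3
    missing_fraction: float = 0.25
    missing_pattern: str = "blocked"  # "blocked" | "random"
    age_blocks: bool = True
    frac_dichotomous: float = 0.4
    frac_timing: float = 0.4
    construct_weights: Optional[np.ndarray] = None
    rating_categories: int = 11
    rating_noise: float = 0.5
    age_range: tuple = (7.0, 82.0)
    orthonormalize_r: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise DimensionMismatchError("missing_fraction must lie in [0, 1)")
        for frac in (self.frac_dichotomous, self.frac_timing):
            if not 0 <= frac <= 1:
                raise DimensionMismatchError("column-type fractions must lie in [0, 1]")
        if self.frac_dichotomous + self.frac_timing > 1:
            raise DimensionMismatchError("dichotomous + timing fractions exceed 1")
        if self.true_d >= min(self.n_persons, self.n_items):
            raise DimensionMismatchError("true_d must be below min(n_persons, n_items)")
        if self.noise_base < 0 or self.row_noise_spread < 0 or self.col_noise_spread < 0:
            raise DimensionMismatchError("noise scales must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class SimulatedTruth:
    """Everything the generator knows that an analyst would not."""

    T: np.ndarray
    R_true: np.ndarray
    C_true: np.ndarray
    row_sds: np.ndarray
    col_sds: np.ndarray
    mask: np.ndarray
    true_construct: Optional[np.ndarray] = None
    ages: Optional[np.ndarray] = None


def _noise_sds(spec: SimulationSpec, rng: np.random.Generator):
    row = np.exp(rng.normal(0.0, spec.row_noise_spread, spec.n_persons))
    col = np.exp(rng.normal(0.0, spec.col_noise_spread, spec.n_items))
    return row, col


def _random_mask(n: int, i: int, fraction: float, floor: int,
                 rng: np.random.Generator, max_tries: int = 20) -> np.ndarray:
    """Random missingness keeping > floor observed cells per row/column."""
    target = int(round(fraction * n * i))
    for _ in range(max_tries):
        mask = np.ones((n, i), dtype=bool)
        order = rng.permutation(n * i)
        row_counts = np.full(n, i)
        col_counts = np.full(i, n)
        removed = 0
        for flat in order:
            r, c = divmod(int(flat), i)
            if row_counts[r] - 1 > floor and col_counts[c] - 1 > floor:
                mask[r, c] = False
                row_counts[r] -= 1
                col_counts[c] -= 1
                removed += 1
                if removed >= target:
                    return mask
        if removed >= target * 0.9:
            return mask
    raise DimensionMismatchError("could not build a feasible missing pattern")


def _blocked_mask(n: int, i: int, fraction: float, groups: np.ndarray) -> np.ndarray:
    """Three overlapping item windows (forms), one per person group.

    Each form covers (1 - fraction) of the items as a contiguous window;
    the windows are staggered so all forms share the central region.
    """
    width = max(int(round((1.0 - fraction) * i)), 1)
    starts = [0, (i - width) // 2, i - width]
    mask = np.zeros((n, i), dtype=bool)
    for g in range(3):
        rows = groups == g
        mask[rows, starts[g]:starts[g] + width] = True
    return mask


def simulate_dataset(spec: SimulationSpec, seed: int = 0):
    """Generate (DataMatrix, SimulatedTruth) from the plain schema.

    All columns are continuous (interval metric); use
    :func:`simulate_instrument` for the mixed-metric screening layout.
    """
    rng = np.random.default_rng(seed)
    n, i, d = spec.n_persons, spec.n_items, spec.true_d
    r_true = rng.standard_normal((n, d))
    if spec.orthonormalize_r:
        q, _ = np.linalg.qr(r_true)
        r_true = q * np.sqrt(n)
    c_true = rng.standard_normal((d, i))
    t = r_true @ c_true
    row_sds, col_sds = _noise_sds(spec, rng)
    noise = rng.standard_normal((n, i)) * spec.noise_base * np.outer(row_sds, col_sds)
    x = t + noise

    if spec.missing_fraction == 0:
        mask = np.ones((n, i), dtype=bool)
    elif spec.missing_pattern == "blocked":
        groups = rng.integers(0, 3, size=n)
        mask = _blocked_mask(n, i, spec.missing_fraction, groups)
    else:
        mask = _random_mask(n, i, spec.missing_fraction, d, rng)

    values = np.where(mask, x, np.nan)
    dm = DataMatrix(
        values,
        [f"p{k:04d}" for k in range(n)],
        [f"i{k:04d}" for k in range(i)],
        {f"i{k:04d}": ColumnMetric("interval") for k in range(i)},
    )
    truth = SimulatedTruth(T=t, R_true=r_true, C_true=c_true,
                           row_sds=row_sds, col_sds=col_sds, mask=mask)
    return dm, truth


def _default_weights(d: int) -> np.ndarray:
    """Construct loadings: mostly the substantive dims, a little age, no difficulty."""
    w = np.ones(d)
    w[0] = 0.3
    if d >= 2:
        w[1] = 0.0
    return w / np.linalg.norm(w)


def simulate_instrument(spec: SimulationSpec, seed: int = 0):
    """Generate the full screening layout.

    Returns (DataMatrix, SimulatedTruth, ages, ratings).  Dimension 0 of
    R_true is standardized log-age (z-scored so its cell contribution is
    on the same footing as the other dimensions); dimension 1 is a
    constant offset carrying item "difficulty".  Timing columns are
    exp-transformed ratio columns whose loadings are negatively related
    to their paired dichotomous items.
    """
    rng = np.random.default_rng(seed)
    n, i, d = spec.n_persons, spec.n_items, spec.true_d
    if d < 3:
        raise DimensionMismatchError("instrument simulation needs true_d >= 3")

    lo, hi = spec.age_range
    ages = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    log_age = np.log(ages)
    z_age = (log_age - log_age.mean()) / log_age.std()

    r_true = rng.standard_normal((n, d))
    r_true[:, 0] = z_age
    r_true[:, 1] = 1.0  # difficulty offset dimension
    c_true = rng.standard_normal((d, i))

    n_dich = int(round(spec.frac_dichotomous * i))
    n_time = min(int(round(spec.frac_timing * i)), n_dich if n_dich else i)
    cols = rng.permutation(i)
    dich_cols = np.sort(cols[:n_dich])
    time_cols = np.sort(cols[n_dich:n_dich + n_time])
    # timing loadings negatively related to their paired response items
    for k, tc in enumerate(time_cols):
        pair = dich_cols[k % len(dich_cols)] if len(dich_cols) else None
        if pair is not None:
            mix = rng.standard_normal(d)
            c_true[:, tc] = -0.75 * c_true[:, pair] + 0.4 * mix
            c_true[1, tc] = rng.standard_normal()  # difficulty stays free

    t = r_true @ c_true
    row_sds, col_sds = _noise_sds(spec, rng)
    noise = rng.standard_normal((n, i)) * spec.noise_base * np.outer(row_sds, col_sds)
    latent = t + noise

    groups = np.digitize(ages, [10.0, 16.0])  # children / teens / adults
    if spec.age_blocks and spec.missing_fraction > 0:
        mask = _blocked_mask(n, i, spec.missing_fraction, groups)
    elif spec.missing_fraction > 0:
        mask = _random_mask(n, i, spec.missing_fraction, d, rng)
    else:
        mask = np.ones((n, i), dtype=bool)

    values = np.array(latent)
    metrics = {}
    col_ids = [f"i{k:04d}" for k in range(i)]
    for j in range(i):
        cid = col_ids[j]
        if j in dich_cols:
            med = np.median(latent[:, j])
            values[:, j] = (latent[:, j] > med).astype(float)
            metrics[cid] = ColumnMetric("dichotomous")
        elif j in time_cols:
            values[:, j] = np.exp(0.5 * latent[:, j] + 2.3)  # lognormal "seconds"
            metrics[cid] = ColumnMetric("ratio")
        else:
            metrics[cid] = ColumnMetric("interval")
    values = np.where(mask, values, np.nan)

    w = (np.asarray(spec.construct_weights, float)
         if spec.construct_weights is not None else _default_weights(d))
    if w.shape != (d,):
        raise DimensionMismatchError("construct_weights length must equal true_d")
    proj = r_true @ w
    k_cat = spec.rating_categories
    noisy = proj + rng.normal(0.0, spec.rating_noise * max(proj.std(), 1e-12), size=n)
    z = (noisy - noisy.mean()) / max(noisy.std(), 1e-12)
    ratings = np.clip(np.round(z * (k_cat / 5.5) + (k_cat - 1) / 2.0), 0, k_cat - 1)

    dm = DataMatrix(values, [f"p{k:04d}" for k in range(n)], col_ids, metrics)
    truth = SimulatedTruth(T=t, R_true=r_true, C_true=c_true,
                           row_sds=row_sds, col_sds=col_sds, mask=mask,
                           true_construct=proj, ages=ages)
    return dm, truth, ages, ratings
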