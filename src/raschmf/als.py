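"""Missing-data alternating least squares with an enforced common space.

The model is X = RC + noise: an N x I observed matrix is factored into
person coordinates R (N x D, orthonormal columns) and item coordinates
C (D x I).  Each half-iteration solves ordinary least squares per row (or
column) using only the non-missing cells; R is re-orthonormalized by QR
every iteration, which plays the role regularization plays in other
factorization methods.  No ridge or lasso penalty is applied anywhere.

Rows or columns may be anchored: fixed C columns support common-item
equating across forms, and a fixed R dimension supports age anchoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamatrix import DataMatrix
from .exceptions import (
    DegenerateSpaceError,
    DimensionMismatchError,
    UnderdeterminedError,
    UnknownAnchorError,
)

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 50
_COND_WARN = 1e10


def dot_estimate(row_coords, col_coords) -> float:
    """Cell estimate: the dot product of a person and an item vector."""
    r = np.asarray(row_coords, dtype=float)
    c = np.asarray(col_coords, dtype=float)
    if r.shape != c.shape or r.ndim != 1:
        raise DimensionMismatchError(
            f"coordinate lengths differ: {r.shape} vs {c.shape}"
        )
    return float(r @ c)


def solve_coordinates(observed, basis, mask=None) -> np.ndarray:
    """Least-squares coordinates from the non-missing entries of one vector.

    Parameters
    ----------
    observed : (n,) vector, possibly containing NaN for missing cells.
    basis : (n, D) matrix whose rows align with the observed entries.
    mask : optional boolean (n,) vector; defaults to finite(observed).

    Rank-deficient systems get the minimum-norm solution with a logged
    condition number; no penalty term is added.
    """
    y = np.asarray(observed, dtype=float)
    a = np.asarray(basis, dtype=float)
    if a.ndim != 2 or a.shape[0] != y.shape[0]:
        raise DimensionMismatchError("basis rows must align with observed entries")
    m = np.isfinite(y) if mask is None else np.asarray(mask, dtype=bool)
    y_obs, a_obs = y[m], a[m]
    d = a.shape[1]
    # exactly-determined systems are allowed here; the calibration and
    # scoring paths enforce their own stricter (overdetermined) floors
    if y_obs.size < d:
        raise UnderdeterminedError(
            f"{y_obs.size} observed values cannot determine {d} coordinates"
        )
    sol, _, rank, sv = np.linalg.lstsq(a_obs, y_obs, rcond=None)
    if rank < d:
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        logger.warning(
            "rank-deficient basis (rank %d < %d, cond %.3g): minimum-norm solution",
            rank, d, cond,
        )
    return sol


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Replace R by the orthonormal factor of its QR decomposition.

    Keeps the column space; a deterministic sign convention (positive
    diagonal of the triangular factor) makes the result unique.
    """
    R = np.asarray(R, dtype=float)
    q, r = np.linalg.qr(R)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-12 * max(diag.max(), 1.0):
        raise DegenerateSpaceError("rank-deficient matrix cannot be orthonormalized")
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


# --------------------------------------------------------------- internals


def _masked_row_solve(x0: np.ndarray, m: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Solve, for every row n, argmin_r ||m_n * (x0_n - basis^T r)||^2.

    x0 must already be zeroed at missing cells; basis is (d, I).
    Vectorized through batched normal equations with a per-row
    minimum-norm fallback when a system is singular.
    """
    d = basis.shape[0]
    # per-row Gram matrices: G_n = basis diag(m_n) basis^T
    cw = basis[None, :, :] * m[:, None, :]            # (N, d, I)
    G = cw @ basis.T                                   # (N, d, d)
    b = x0 @ basis.T                                   # (N, d)
    try:
        return np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(b)
        for n in range(x0.shape[0]):
            sol, _, rank, sv = np.linalg.lstsq(G[n], b[n], rcond=None)
            if rank < d:
                logger.warning("singular system in row %d: minimum-norm solution", n)
            out[n] = sol
        return out


def _orthonormalize_with_anchors(R: np.ndarray, anchor_idx: np.ndarray) -> np.ndarray:
    """QR-orthonormalize the free columns of R against the anchored ones.

    Anchored columns are assumed unit-normalized and mutually orthonormal;
    they are left untouched.
    """
    if anchor_idx.size == 0:
        return orthonormalize(R)
    out = R.copy()
    qa = R[:, anchor_idx]
    free = np.setdiff1d(np.arange(R.shape[1]), anchor_idx)
    if free.size:
        rf = R[:, free] - qa @ (qa.T @ R[:, free])
        out[:, free] = orthonormalize(rf)
    return out


@dataclass
class CoordinateSet:
    """Fitted person (R) and item (C) coordinates with provenance.

    ``R`` is N x D with orthonormal columns after an unanchored
    calibration (anchored dimensions are unit-normalized only, and the
    final person-solve of an age-anchored calibration relaxes
    orthonormality by design); ``C`` is D x I.
    """

    R: np.ndarray
    C: np.ndarray
    dimensionality: int
    seed: int
    anchored_cols: set = field(default_factory=set)
    anchored_dims: set = field(default_factory=set)
    converged: bool = True
    n_iter: int = 0
    row_ids: Optional[list] = None
    col_ids: Optional[list] = None
    dropped_rows: list = field(default_factory=list)
    dropped_cols: list = field(default_factory=list)
    rms_history: list = field(default_factory=list)

    @property
    def estimates(self) -> np.ndarray:
        """E = RC, covering observed and missing cells alike."""
        return self.R @ self.C


class ALSFactorization:
    """Scikit-learn style estimator for masked alternating least squares.

    Parameters
    ----------
    n_dims : int
        Dimensionality D of the common space; must satisfy D < min(N, I).
    tol : float
        Convergence threshold on the RMS change of E over observed cells.
    max_iter : int
        Iteration cap; convergence usually arrives well before 20.
    seed : int
        Seed for the random standard-normal initialization of C.
    n_starts : int
        Number of random restarts.  Structured (e.g. blocked) missing
        patterns give alternating least squares genuine local minima; the
        start with the lowest observed-cell RMS residual is kept.  With
        the default of 1 the given seed is used directly.
    anchored_cols : dict, optional
        {column index: length-D vector} of C columns held fixed (equating).
    anchored_dims : dict, optional
        {dimension index: length-N unit vector} of R columns held fixed
        (age anchoring).  Free dimensions are orthonormalized against them.
    drop_sparse : bool
        Exclude rows/columns with <= n_dims observed cells from the
        calibration (with a logged warning) instead of erroring out.

    Attributes
    ----------
    R_, C_, E_ : fitted coordinates and estimates (NaN on dropped slices).
    converged_, n_iter_, rms_history_ : convergence metadata.
    dropped_rows_, dropped_cols_ : indices excluded from calibration.
    """

    def __init__(self, n_dims=1, tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER,
                 seed=0, anchored_cols=None, anchored_dims=None, drop_sparse=True,
                 n_starts=1):
        self.n_dims = n_dims
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed
        self.anchored_cols = anchored_cols
        self.anchored_dims = anchored_dims
        self.drop_sparse = drop_sparse
        self.n_starts = n_starts

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep=True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_dims", "tol", "max_iter", "seed",
            "anchored_cols", "anchored_dims", "drop_sparse", "n_starts")}

    def set_params(self, **params) -> "ALSFactorization":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------- fitting

    def fit(self, X, mask=None) -> "ALSFactorization":
        x = np.array(X, dtype=float)
        m = np.isfinite(x) if mask is None else np.asarray(mask, dtype=bool)
        x = np.where(m, x, np.nan)
        n, i = x.shape
        d = int(self.n_dims)
        if d < 1 or d >= min(n, i):
            raise DimensionMismatchError(f"need 1 <= D < min(N, I); got D={d}")

        keep_rows, keep_cols = self._usable(m, d)
        self.dropped_rows_ = sorted(set(range(n)) - set(keep_rows))
        self.dropped_cols_ = sorted(set(range(i)) - set(keep_cols))
        xs, ms = x[np.ix_(keep_rows, keep_cols)], m[np.ix_(keep_rows, keep_cols)]

        anchored_cols = dict(self.anchored_cols or {})
        anchored_dims = dict(self.anchored_dims or {})
        col_pos = {c: k for k, c in enumerate(keep_cols)}
        try:
            anchored_cols = {col_pos[c]: np.asarray(v, float) for c, v in anchored_cols.items()}
        except KeyError as exc:
            raise UnknownAnchorError(f"anchored column {exc} not in calibrated data")
        anchored_dims = {
            dim: np.asarray(v, float)[keep_rows] for dim, v in anchored_dims.items()
        }
        for dim in anchored_dims:
            if dim < 0 or dim >= d:
                raise UnknownAnchorError(f"anchored dimension {dim} outside 0..{d - 1}")

        n_starts = max(int(self.n_starts), 1)
        if n_starts == 1:
            start_seeds = [int(self.seed)]
        else:
            start_seeds = [int(s) for s in
                           np.random.SeedSequence(self.seed).generate_state(n_starts)
                           % (2**31)]
        best = None
        for s in start_seeds:
            cand = self._als(xs, ms, d, anchored_cols, anchored_dims, s)
            rms = cand[4][-1]
            key = (not cand[2], rms)  # prefer converged, then lowest RMS
            if best is None or key < best[0]:
                best = (key, cand)
            if cand[2] and rms < max(self.tol * 100, 1e-10):
                break
        R, C, conv, n_iter, history = best[1]

        self.R_ = np.full((n, d), np.nan)
        self.C_ = np.full((d, i), np.nan)
        self.R_[keep_rows] = R
        self.C_[:, keep_cols] = C
        self.E_ = self.R_ @ self.C_
        self.converged_ = conv
        self.n_iter_ = n_iter
        self.rms_history_ = history
        return self

    def _usable(self, m: np.ndarray, d: int):
        """Iteratively drop rows/columns with too few observed cells."""
        keep_r = np.ones(m.shape[0], dtype=bool)
        keep_c = np.ones(m.shape[1], dtype=bool)
        if not self.drop_sparse:
            return np.where(keep_r)[0], np.where(keep_c)[0]
        while True:
            sub = m[np.ix_(keep_r, keep_c)]
            bad_r = sub.sum(axis=1) <= d
            bad_c = sub.sum(axis=0) <= d
            if not bad_r.any() and not bad_c.any():
                break
            keep_r[np.where(keep_r)[0][bad_r]] = False
            keep_c[np.where(keep_c)[0][bad_c]] = False
            if keep_r.sum() <= d or keep_c.sum() <= d:
                raise UnderdeterminedError(
                    "too few rows/columns with more than D observations"
                )
        n_drop = (~keep_r).sum() + (~keep_c).sum()
        if n_drop:
            logger.warning("dropped %d sparse rows/columns (<= D observations)", n_drop)
        return np.where(keep_r)[0], np.where(keep_c)[0]

    def _als(self, x, m, d, anchored_cols, anchored_dims, seed=None):
        n, i = x.shape
        rng = np.random.default_rng(self.seed if seed is None else seed)
        mf = m.astype(float)
        x0 = np.where(m, x, 0.0)

        C = rng.standard_normal((d, i))
        for j, vec in anchored_cols.items():
            C[:, j] = vec
        anchor_dim_idx = np.array(sorted(anchored_dims), dtype=int)
        free_dims = np.setdiff1d(np.arange(d), anchor_dim_idx)
        R = np.zeros((n, d))
        for dim, vec in anchored_dims.items():
            R[:, dim] = vec

        anchored_col_idx = np.array(sorted(anchored_cols), dtype=int)
        free_col_idx = np.setdiff1d(np.arange(i), anchored_col_idx)
        prev_e_obs = None
        converged = False
        history = []
        it = 0
        for it in range(1, self.max_iter + 1):
            # --- R half-iteration (free dimensions only)
            mf_r, x0_r = mf, x0
            if anchored_col_idx.size and it == 1:
                # the anchors alone define the reference frame; the first
                # person solve must not be polluted by the random free C
                keep = np.zeros(i, dtype=bool)
                keep[anchored_col_idx] = True
                mf_r = mf * keep
                x0_r = x0 * keep
            if anchor_dim_idx.size:
                resid = x0_r - mf_r * (R[:, anchor_dim_idx] @ C[anchor_dim_idx])
                R[:, free_dims] = _masked_row_solve(resid, mf_r, C[free_dims])
            else:
                R = _masked_row_solve(x0_r, mf_r, C)
            if not anchored_col_idx.size:
                # QR would rotate R out of the frame the anchored C
                # columns live in, so it only runs when C is fully free
                R = _orthonormalize_with_anchors(R, anchor_dim_idx)

            # --- C half-iteration (free columns only)
            C_new = _masked_row_solve(x0.T, mf.T, R.T).T
            if free_col_idx.size < i:
                C[:, free_col_idx] = C_new[:, free_col_idx]
            else:
                C = C_new

            e_obs = (R @ C)[m]
            history.append(float(np.sqrt(np.mean((x[m] - e_obs) ** 2))))
            if prev_e_obs is not None:
                delta = float(np.sqrt(np.mean((e_obs - prev_e_obs) ** 2)))
                if delta < self.tol:
                    converged = True
                    prev_e_obs = e_obs
                    break
            prev_e_obs = e_obs
        if not converged:
            logger.warning("ALS did not converge in %d iterations", self.max_iter)
        return R, C, converged, it, history

    # ------------------------------------------------------------- scoring

    def transform(self, X, mask=None) -> np.ndarray:
        """Person coordinates for new rows against the fitted C.

        Rows with too few observations (<= D) come back as NaN with a
        warning rather than failing the batch.
        """
        if not hasattr(self, "C_"):
            raise RuntimeError("transform called before fit")
        x = np.atleast_2d(np.asarray(X, dtype=float))
        m = np.isfinite(x) if mask is None else np.atleast_2d(np.asarray(mask, dtype=bool))
        d = self.C_.shape[0]
        usable_cols = np.all(np.isfinite(self.C_), axis=0)
        out = np.full((x.shape[0], d), np.nan)
        for nrow in range(x.shape[0]):
            mm = m[nrow] & usable_cols
            if mm.sum() <= d:
                warnings.warn(f"row {nrow}: {int(mm.sum())} observations <= D, skipped")
                continue
            out[nrow] = solve_coordinates(x[nrow, mm], self.C_[:, mm].T)
        return out

    def fit_transform(self, X, mask=None) -> np.ndarray:
        return self.fit(X, mask=mask).R_


def als_decompose(X, d: int, seed: int = 0, *, tol=DEFAULT_TOL,
                  max_iter=DEFAULT_MAX_ITER, anchored_cols=None,
                  anchored_dims=None, drop_sparse=True,
                  n_starts=1) -> CoordinateSet:
    """Decompose a DataMatrix (or bare array) at dimensionality ``d``.

    Thin wrapper over :class:`ALSFactorization` returning a
    :class:`CoordinateSet`.  ``anchored_cols`` maps column *ids* (or
    indices for bare arrays) to fixed C vectors; ``anchored_dims`` maps R
    dimension indices to fixed unit-norm person vectors.
    """
    if isinstance(X, DataMatrix):
        values, row_ids, col_ids = X.values, X.row_ids, X.col_ids
    else:
        values = np.asarray(X, dtype=float)
        row_ids = [str(k) for k in range(values.shape[0])]
        col_ids = [str(k) for k in range(values.shape[1])]

    anchored_cols = anchored_cols or {}
    col_index = {c: k for k, c in enumerate(col_ids)}
    anchored_by_idx = {}
    for key, vec in anchored_cols.items():
        idx = key if isinstance(key, (int, np.integer)) else col_index.get(key)
        if idx is None or not (0 <= int(idx) < len(col_ids)):
            raise UnknownAnchorError(f"anchored column id {key!r} not present")
        anchored_by_idx[int(idx)] = vec

    est = ALSFactorization(
        n_dims=d, tol=tol, max_iter=max_iter, seed=seed,
        anchored_cols=anchored_by_idx, anchored_dims=anchored_dims,
        drop_sparse=drop_sparse, n_starts=n_starts,
    ).fit(values)

    return CoordinateSet(
        R=est.R_, C=est.C_, dimensionality=d, seed=seed,
        anchored_cols={col_ids[j] for j in anchored_by_idx},
        anchored_dims=set((anchored_dims or {}).keys()),
        converged=est.converged_, n_iter=est.n_iter_,
        row_ids=list(row_ids), col_ids=list(col_ids),
        dropped_rows=[row_ids[j] for j in est.dropped_rows_],
        dropped_cols=[col_ids[j] for j in est.dropped_cols_],
        rms_history=est.rms_history_,
    )
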