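"""Age-anchored calibration, common-item equating, item drift, item banks.

Equating rests on the specific-objectivity property: once dimensionality
is correct, item coordinates are invariant (up to an arbitrary rotation of
the space) to the persons used to calibrate them, so fixing ("anchoring")
the coordinates of shared items places a new form in the reference
coordinate system in a single least-squares pass.

Age-anchored calibration removes a known nuisance dimension explicitly:
standardized log-age is installed as the first person dimension, item
loadings on it are solved directly, the residual structure is factored at
the chosen residual dimensionality, and a final refinement re-solves C
then R so person coordinates are computed last.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.stats import pearsonr

from . import __version__
from .als import ALSFactorization, CoordinateSet, _masked_row_solve, als_decompose
from .datamatrix import DataMatrix
from .errors import NoiseModel
from .exceptions import AssemblyError, DimensionMismatchError, EquatingError
from .metrics import ColumnMetric, to_pseudologit

logger = logging.getLogger(__name__)


def standardize_unit_norm(v: np.ndarray) -> np.ndarray:
    """Center a vector and scale it to unit Euclidean norm."""
    v = np.asarray(v, dtype=float)
    centered = v - v.mean()
    norm = np.linalg.norm(centered)
    if norm <= 0:
        raise DimensionMismatchError("constant vector cannot be unit-normalized")
    return centered / norm


def age_regression(X, ages: np.ndarray):
    """First factorization pass: regress every column on standardized log-age.

    Returns (age_vector, c1, residual_matrix).  Each residual column is,
    by the least-squares normal equations, orthogonal to the age vector
    over its observed cells.
    """
    x = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    ages = np.asarray(ages, dtype=float)
    bad = ~(np.isfinite(ages) & (ages > 0))
    if bad.any():
        ids = (X.row_ids if isinstance(X, DataMatrix)
               else [str(k) for k in range(x.shape[0])])
        raise DimensionMismatchError(
            "missing/invalid age for persons: "
            + ", ".join(ids[k] for k in np.where(bad)[0][:20])
        )
    a = standardize_unit_norm(np.log(ages))
    mask = np.isfinite(x)
    x0 = np.where(mask, x, 0.0)
    num = a @ x0
    den = (a**2) @ mask
    c1 = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    res = np.where(mask, x - np.outer(a, c1), np.nan)
    return a, c1, res


def _refine(x: np.ndarray, mask: np.ndarray, R: np.ndarray,
            tol: float, max_iter: int):
    """Alternating C-then-R refinement sweeps ending with the person solve.

    R is orthonormalized (span-preserving, so the estimates are untouched)
    before each column solve to keep the alternation well conditioned;
    every sweep ends with the row solve, so person coordinates are always
    the last quantity computed.
    """
    from .als import orthonormalize  # deferred: avoid import noise at module load

    mf = mask.astype(float)
    x0 = np.where(mask, x, 0.0)
    prev = None
    converged = False
    it = 0
    C = None
    for it in range(1, max_iter + 1):
        C = _masked_row_solve(x0.T, mf.T, orthonormalize(R).T).T
        R = _masked_row_solve(x0, mf, C)
        e_obs = (R @ C)[mask]
        if prev is not None and float(np.sqrt(np.mean((e_obs - prev) ** 2))) < tol:
            converged = True
            break
        prev = e_obs
    return R, C, converged, it


def age_anchored_calibration(X, ages, d_residual: int, seed: int = 0, *,
                             tol: float = 1e-6, max_iter: int = 50,
                             refine_max_iter: Optional[int] = None,
                             n_starts: int = 3) -> CoordinateSet:
    """Multistep factorization with log-age as the first dimension.

    1. standardize log(age) to unit norm as R[:, 0];
    2. solve each item's age loading C[0] by least squares, form the
       residual matrix;
    3. ALS on the residuals at ``d_residual`` for the remaining dimensions;
    4. append them to the age dimension;
    5. final refinement — alternating C-then-R sweeps (person coordinates
       computed last) iterated to the ALS tolerance, with the age
       coordinate re-estimated freely.

    Total dimensionality is ``d_residual + 1``.
    """
    if isinstance(X, DataMatrix):
        x, row_ids, col_ids = X.values, X.row_ids, X.col_ids
    else:
        x = np.asarray(X, dtype=float)
        row_ids = [str(k) for k in range(x.shape[0])]
        col_ids = [str(k) for k in range(x.shape[1])]
    if d_residual < 1:
        raise DimensionMismatchError("d_residual must be >= 1")

    a, _, res = age_regression(X, ages)
    resid_fit = ALSFactorization(
        n_dims=d_residual, seed=seed, tol=tol, max_iter=max_iter,
        n_starts=n_starts,
    ).fit(res)
    r_res = np.where(np.isfinite(resid_fit.R_), resid_fit.R_, 0.0)
    r_pen = np.column_stack([a, r_res])

    mask = np.isfinite(x)
    refine_iters = refine_max_iter if refine_max_iter is not None else max(max_iter, 50)
    R, C, converged, n_ref = _refine(x, mask, r_pen, tol, refine_iters)

    return CoordinateSet(
        R=R, C=C, dimensionality=d_residual + 1, seed=seed,
        anchored_dims={0}, converged=converged and resid_fit.converged_,
        n_iter=resid_fit.n_iter_ + n_ref,
        row_ids=list(row_ids), col_ids=list(col_ids),
    )


# ------------------------------------------------------------------ banking


@dataclass
class ItemBank:
    """Calibrated per-item coordinates, metrics and error coordinates.

    ``items`` maps item id to a record holding the estimate coordinates
    (length D), 2-dimensional EAR and SE coordinates with their per-item
    polyfit coefficients, the fitted column metric, observation count and
    mean calibration EAR.  ``constructs`` maps a construct name to its
    coordinates plus the scale transform onto the reporting scale.
    """

    dimensionality: int
    items: dict
    constructs: dict = field(default_factory=dict)
    cut_scores: tuple = (45.0, 50.0, 55.0)
    provenance: dict = field(default_factory=dict)
    schema_version: int = 1

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cut_scores)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise AssemblyError("cut scores must be strictly increasing")
        self.cut_scores = cuts
        for iid, rec in self.items.items():
            if len(np.asarray(rec["coords"])) != self.dimensionality:
                raise AssemblyError(f"item {iid}: coordinate length != D")
        for name, rec in self.constructs.items():
            if len(np.asarray(rec["coords"])) != self.dimensionality:
                raise AssemblyError(f"construct {name}: coordinate length != D")

    @property
    def item_ids(self) -> list:
        return list(self.items)

    def coords_matrix(self, ids) -> np.ndarray:
        """D x m matrix of estimate coordinates for the given item ids."""
        return np.column_stack([np.asarray(self.items[i]["coords"], float) for i in ids])

    # ------------------------------------------------------------- persist

    def to_json(self) -> str:
        def enc(rec):
            out = {}
            for k, v in rec.items():
                if isinstance(v, ColumnMetric):
                    out[k] = v.to_dict()
                elif isinstance(v, np.ndarray):
                    out[k] = v.tolist()
                elif hasattr(v, "to_dict"):
                    out[k] = v.to_dict()
                else:
                    out[k] = v
            return out

        payload = {
            "schema_version": self.schema_version,
            "dimensionality": self.dimensionality,
            "cut_scores": list(self.cut_scores),
            "provenance": self.provenance,
            "items": {iid: enc(rec) for iid, rec in self.items.items()},
            "constructs": {name: enc(rec) for name, rec in self.constructs.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ItemBank":
        from .scoring import ScaleTransform  # local import avoids a cycle

        payload = json.loads(text)
        items = {}
        for iid, rec in payload["items"].items():
            dec = dict(rec)
            dec["metric"] = ColumnMetric.from_dict(rec["metric"])
            for key in ("coords", "ear_coords", "ear_polyfit", "se_coords", "se_polyfit"):
                dec[key] = np.asarray(rec[key], dtype=float)
            items[iid] = dec
        constructs = {}
        for name, rec in payload["constructs"].items():
            constructs[name] = {
                "coords": np.asarray(rec["coords"], dtype=float),
                "transform": ScaleTransform.from_dict(rec["transform"]),
            }
        return cls(
            dimensionality=int(payload["dimensionality"]),
            items=items,
            constructs=constructs,
            cut_scores=tuple(payload["cut_scores"]),
            provenance=payload.get("provenance", {}),
            schema_version=int(payload.get("schema_version", 1)),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ItemBank":
        return cls.from_json(Path(path).read_text())


def build_item_bank(coords: CoordinateSet, noise: NoiseModel, metrics: dict,
                    construct_coords, transform, cut_scores=(45.0, 50.0, 55.0),
                    construct_id: str = "construct", seed: Optional[int] = None) -> ItemBank:
    """Assemble the calibration outputs into a serializable bank."""
    d = coords.dimensionality
    if noise.d != d:
        raise AssemblyError(f"noise model d={noise.d} != calibration D={d}")
    w = np.asarray(construct_coords, dtype=float)
    if w.shape != (d,):
        raise AssemblyError("construct coordinates length != D")

    obs = np.isfinite(noise.residuals)
    items = {}
    for j, iid in enumerate(coords.col_ids):
        cvec = coords.C[:, j]
        if not np.all(np.isfinite(cvec)):
            logger.warning("item %s dropped during calibration; not banked", iid)
            continue
        col_obs = obs[:, j]
        items[iid] = {
            "metric": metrics.get(iid, ColumnMetric("interval", fitted=True)),
            "coords": np.asarray(cvec, float),
            "ear_coords": np.asarray(noise.ear_col_coords[:, j], float),
            "ear_polyfit": np.asarray(noise.ear_polyfit[j], float),
            "se_coords": np.asarray(noise.se_col_coords[:, j], float),
            "se_polyfit": np.asarray(noise.se_polyfit[j], float),
            "n_obs": int(noise.col_counts[j]),
            "mean_ear": float(np.mean(noise.ear[col_obs, j])) if col_obs.any() else float("nan"),
        }
    return ItemBank(
        dimensionality=d,
        items=items,
        constructs={construct_id: {"coords": w, "transform": transform}},
        cut_scores=tuple(cut_scores),
        provenance={
            "seed": int(seed if seed is not None else coords.seed),
            "calibration_date": datetime.date.today().isoformat(),
            "software_version": __version__,
        },
    )


# ----------------------------------------------------------------- equating


@dataclass
class EquatingReport:
    """Common-item fit after grafting reference coordinates onto a new form."""

    common_ids: list
    rmse_per_item: dict
    outfit_per_item: dict
    overall_rmse: float
    equated: bool
    fitted_metrics: dict = field(default_factory=dict)


def equate_forms(reference_bank: ItemBank, X_B, common_ids=None, *,
                 min_common: Optional[int] = None,
                 outfit_threshold: float = 2.0):
    """Place Form B in the reference bank's coordinate system.

    Common items keep their banked C vectors (and banked pseudo-logit
    parameters); Form B person coordinates are solved in one
    least-squares pass from those anchors, then the new items' C vectors
    are solved from the person coordinates.  Returns the Form B
    CoordinateSet and a common-item fit report.
    """
    if not isinstance(X_B, DataMatrix):
        X_B = DataMatrix(np.asarray(X_B, float),
                         [str(k) for k in range(np.asarray(X_B).shape[0])],
                         [str(k) for k in range(np.asarray(X_B).shape[1])])
    d = reference_bank.dimensionality
    bank_ids = set(reference_bank.item_ids)
    if common_ids is None:
        common = [c for c in X_B.col_ids if c in bank_ids]
    else:
        common = [str(c) for c in common_ids]
        missing = [c for c in common if c not in bank_ids or c not in X_B.col_ids]
        if missing:
            raise EquatingError(f"common items absent from bank or data: {missing}")
    floor = min_common if min_common is not None else 2 * d
    if len(common) <= d:
        raise EquatingError(
            f"{len(common)} common items cannot identify a {d}-dimensional link"
        )
    if len(common) < floor:
        raise EquatingError(
            f"{len(common)} common items below the required floor of {floor}"
        )

    col_pos = {c: j for j, c in enumerate(X_B.col_ids)}
    n, i = X_B.shape
    x_pl = np.full((n, i), np.nan)
    fitted_metrics = {}
    for j, cid in enumerate(X_B.col_ids):
        metric = (reference_bank.items[cid]["metric"] if cid in bank_ids
                  else X_B.metric_for(cid))
        x_pl[:, j], fitted_metrics[cid] = to_pseudologit(X_B.values[:, j], metric)

    mask = np.isfinite(x_pl)
    c_anchor = reference_bank.coords_matrix(common)          # D x m
    common_idx = np.array([col_pos[c] for c in common])
    mf_common = mask[:, common_idx].astype(float)
    x0_common = np.where(mask[:, common_idx], x_pl[:, common_idx], 0.0)
    enough = mf_common.sum(axis=1) > d
    R = np.full((n, d), np.nan)
    if enough.any():
        R[enough] = _masked_row_solve(x0_common[enough], mf_common[enough], c_anchor)
    if not enough.all():
        logger.warning("%d persons with <= D common responses left unscored",
                       int((~enough).sum()))

    C = np.full((d, i), np.nan)
    C[:, common_idx] = c_anchor
    new_idx = np.setdiff1d(np.arange(i), common_idx)
    if new_idx.size:
        rows_ok = np.all(np.isfinite(R), axis=1)
        mf_new = (mask[:, new_idx] & rows_ok[:, None]).astype(float)
        x0_new = np.where(mask[:, new_idx] & rows_ok[:, None], x_pl[:, new_idx], 0.0)
        C[:, new_idx] = _masked_row_solve(x0_new.T, mf_new.T, R.T).T

    e = R @ C
    rmse_per_item, outfit_per_item = {}, {}
    for cid, j in zip(common, common_idx):
        obs = mask[:, j] & np.isfinite(e[:, j])
        res = x_pl[obs, j] - e[obs, j]
        rmse = float(np.sqrt(np.mean(res**2))) if obs.any() else float("nan")
        rmse_per_item[cid] = rmse
        mean_ear = reference_bank.items[cid].get("mean_ear")
        outfit_per_item[cid] = (rmse / mean_ear
                                if mean_ear and np.isfinite(mean_ear) and mean_ear > 0
                                else float("nan"))
    finite_rmse = [v for v in rmse_per_item.values() if np.isfinite(v)]
    overall = float(np.sqrt(np.mean(np.square(finite_rmse)))) if finite_rmse else float("nan")
    finite_outfit = [v for v in outfit_per_item.values() if np.isfinite(v)]
    equated = all(v < outfit_threshold for v in finite_outfit) if finite_outfit else True
    if not equated:
        logger.warning("equating failed: common-item outfit exceeds %.2f", outfit_threshold)

    coord_set = CoordinateSet(
        R=R, C=C, dimensionality=d, seed=reference_bank.provenance.get("seed", 0),
        anchored_cols=set(common), converged=True, n_iter=1,
        row_ids=list(X_B.row_ids), col_ids=list(X_B.col_ids),
    )
    report = EquatingReport(
        common_ids=common, rmse_per_item=rmse_per_item,
        outfit_per_item=outfit_per_item, overall_rmse=overall,
        equated=equated, fitted_metrics=fitted_metrics,
    )
    return coord_set, report


# -------------------------------------------------------------------- drift


@dataclass
class DriftReport:
    """Item-coordinate reproducibility across examinee groups."""

    per_item: dict
    per_dimension: np.ndarray
    pooled: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"item": list(self.per_item), "r": list(self.per_item.values())}
        )


def item_drift(C_group1: np.ndarray, C_group2: np.ndarray, shared_ids,
               ids1=None, ids2=None, align: bool = False) -> DriftReport:
    """Correlate item coordinates calibrated on two person groups.

    Both C matrices are D x I; ``ids1``/``ids2`` give their column ids
    (defaulting to ``shared_ids`` order for both).  With ``align=True``
    the second group's coordinates are rotated onto the first by
    orthogonal Procrustes over the shared items — needed when the groups
    were calibrated independently rather than against common anchors.

    Reports the Pearson correlation per item (across dimensions), per
    dimension (across items) and pooled over all entries.
    """
    shared = [str(s) for s in shared_ids]
    if not shared:
        raise EquatingError("no shared items to compare")
    c1 = np.asarray(C_group1, dtype=float)
    c2 = np.asarray(C_group2, dtype=float)
    ids1 = [str(s) for s in (ids1 if ids1 is not None else shared)]
    ids2 = [str(s) for s in (ids2 if ids2 is not None else shared)]
    pos1 = {c: j for j, c in enumerate(ids1)}
    pos2 = {c: j for j, c in enumerate(ids2)}
    missing = [s for s in shared if s not in pos1 or s not in pos2]
    if missing:
        raise EquatingError(f"shared items absent from a group: {missing}")
    a = c1[:, [pos1[s] for s in shared]]
    b = c2[:, [pos2[s] for s in shared]]
    if align:
        rot, _ = orthogonal_procrustes(b.T, a.T)
        b = (b.T @ rot).T

    d = a.shape[0]
    per_item = {}
    for k, s in enumerate(shared):
        if d >= 2 and np.std(a[:, k]) > 0 and np.std(b[:, k]) > 0:
            per_item[s] = float(pearsonr(a[:, k], b[:, k])[0])
        else:
            per_item[s] = float("nan")
    per_dim = np.full(d, np.nan)
    if len(shared) >= 2:
        for dim in range(d):
            if np.std(a[dim]) > 0 and np.std(b[dim]) > 0:
                per_dim[dim] = pearsonr(a[dim], b[dim])[0]
    pooled = float(pearsonr(a.ravel(), b.ravel())[0])
    return DriftReport(per_item=per_item, per_dimension=per_dim, pooled=pooled)
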