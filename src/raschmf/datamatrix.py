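"""Persons x items response container with arbitrary missing cells.

CSV layout: first column = person id, header row = item ids, empty cell =
missing.  Column metrics travel in a JSON sidecar (list of
``{col_id, kind, n_categories, location, scale}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateColumnError, DimensionMismatchError
from .metrics import ColumnMetric, to_pseudologit


@dataclass
class DataMatrix:
    """Rectangular response matrix, NaN marking missing cells."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    col_metrics: Optional[dict] = None  # col_id -> ColumnMetric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionMismatchError("values must be a 2-d matrix")
        n, i = self.values.shape
        if n < 1 or i < 1:
            raise DimensionMismatchError("matrix must be at least 1x1")
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n or len(self.col_ids) != i:
            raise DimensionMismatchError("id lists must match matrix shape")
        if len(set(self.row_ids)) != n or len(set(self.col_ids)) != i:
            raise DimensionMismatchError("row and column ids must be unique")
        mask = self.mask
        if not mask.any(axis=1).all():
            raise DegenerateColumnError("every row must retain at least one observed cell")
        if not mask.any(axis=0).all():
            raise DegenerateColumnError("every column must retain at least one observed cell")

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where a cell is observed."""
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def metric_for(self, col_id: str) -> ColumnMetric:
        if self.col_metrics and col_id in self.col_metrics:
            return self.col_metrics[col_id]
        return ColumnMetric("interval")

    def to_pseudologit(self) -> tuple["DataMatrix", dict]:
        """Convert every column to the pseudo-logit metric.

        Returns a new DataMatrix plus the dict of fitted metrics
        (col_id -> ColumnMetric) for persistence in an item bank.
        Zero-variance columns raise DegenerateColumnError.
        """
        out = np.full_like(self.values, np.nan)
        fitted = {}
        for j, cid in enumerate(self.col_ids):
            out[:, j], fitted[cid] = to_pseudologit(self.values[:, j], self.metric_for(cid))
        return DataMatrix(out, self.row_ids, self.col_ids, fitted), fitted

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path, metrics_path=None) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        df.index.name = "person_id"
        df.to_csv(path)
        if metrics_path is not None and self.col_metrics is not None:
            save_metrics(self.col_metrics, metrics_path)

    @classmethod
    def from_csv(cls, path, metrics_path=None) -> "DataMatrix":
        df = pd.read_csv(path, index_col=0)
        metrics = load_metrics(metrics_path) if metrics_path else None
        return cls(
            df.to_numpy(dtype=float),
            [str(r) for r in df.index],
            [str(c) for c in df.columns],
            metrics,
        )


def save_metrics(metrics: dict, path) -> None:
    payload = [{"col_id": cid, **m.to_dict()} for cid, m in metrics.items()]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_metrics(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {entry["col_id"]: ColumnMetric.from_dict(entry) for entry in payload}
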