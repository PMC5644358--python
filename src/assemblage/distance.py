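"""Labeled symmetric distance matrices with TSV serialization."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = ["DistanceMatrix"]


class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative matrix with sample labels."""

    _SYM_TOL = 1e-12

    def __init__(self, values, labels: Sequence[str]):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if values.shape[0] != len(labels):
            raise ValueError("labels length does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        if not np.allclose(values, values.T, atol=self._SYM_TOL, rtol=0.0):
            raise ValueError("matrix is not symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > self._SYM_TOL:
            raise ValueError("diagonal is not zero")
        if (values < -self._SYM_TOL).any():
            raise ValueError("negative distances")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self._values = values
        self._labels = tuple(labels)

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n(self) -> int:
        return len(self._labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangular entries in scipy ``squareform`` order."""
        return squareform(self._values, checks=False)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = {lab: i for i, lab in enumerate(self._labels)}
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        order = [idx[lab] for lab in labels]
        return DistanceMatrix(self._values[np.ix_(order, order)], list(labels))

    def filter(self, labels: Sequence[str]) -> "DistanceMatrix":
        return self.reorder(labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._labels, columns=self._labels)

    def write(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError(f"row/column labels differ in {path}")
        return cls(df.to_numpy(dtype=float), df.index.astype(str).tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self._labels == other._labels and np.array_equal(self._values, other._values)

    def __repr__(self) -> str:
        return f"<DistanceMatrix n={self.n}>"
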