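"""Labeled symmetric relationship matrices shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_KINDS = ("A", "G", "Gs", "K", "I")

SYMMETRY_TOL = 1e-12


@dataclass
class RelationshipMatrix:
    """A symmetric additive-relationship matrix labeled by line ids.

    Parameters
    ----------
    ids : list of str
        Ordered line identifiers; one per row/column.
    values : ndarray of shape (n, n)
        Symmetric matrix of additive relationships (unitless).
    kind : str
        One of ``A`` (pedigree), ``G`` (genomic), ``Gs`` (rescaled genomic),
        ``K`` (blended) or ``I`` (identity / generic).
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "K"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but matrix of shape {self.values.shape}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in relationship matrix")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        asym = np.max(np.abs(self.values - self.values.T)) if len(self.ids) else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
        # tolerate float noise below the contract tolerance by symmetrizing
        self.values = 0.5 * (self.values + self.values.T)
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def restrict(self, subset_ids: list[str]) -> "RelationshipMatrix":
        """Return the principal submatrix for ``subset_ids`` (in that order)."""
        missing = [i for i in subset_ids if i not in self._index]
        if missing:
            raise KeyError(f"ids not present in {self.kind} matrix: {missing[:10]}")
        idx = np.array([self._index[i] for i in subset_ids], dtype=int)
        return RelationshipMatrix(list(subset_ids), self.values[np.ix_(idx, idx)], self.kind)

    def aligned_values(self, ids: list[str]) -> np.ndarray:
        """Values re-ordered to ``ids`` without copying semantics changes."""
        return self.restrict(list(ids)).values

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def write_relmat(mat: RelationshipMatrix, path: str) -> None:
    """Write a square CSV: header row / first column are ids, 12 significant digits."""
    frame = mat.to_frame()
    frame.to_csv(path, float_format="%.12g", index_label="id")


def read_relmat(path: str, kind: str = "K") -> RelationshipMatrix:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"row/column ids disagree in {path}")
    return RelationshipMatrix(list(frame.index), frame.to_numpy(dtype=float), kind)


def check_alignment(left: RelationshipMatrix, right: RelationshipMatrix) -> None:
    """Raise with the asymmetric id difference if the two matrices disagree."""
    ls, rs = set(left.ids), set(right.ids)
    if ls != rs:
        only_left = sorted(ls - rs)[:10]
        only_right = sorted(rs - ls)[:10]
        raise ValueError(
            "relationship matrices are not aligned: "
            f"only in {left.kind}: {only_left}; only in {right.kind}: {only_right}"
        )
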