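"""Typed containers and delimited-text I/O for association and similarity data.

The on-disk dialect is tab-separated text: the header row carries column
identifiers, the first column carries row identifiers, identifiers are
opaque strings (e.g. ``CID:3385``, ``hsa-mir-21``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "MatrixParseError",
    "AssociationMatrix",
    "SimilarityMatrix",
    "DatasetBundle",
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "count_unknown",
]

SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """An in-memory matrix violates a container invariant."""


class MatrixParseError(ValueError):
    """A delimited-text matrix file could not be parsed."""


def _check_unique(ids: Sequence[str], label: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {label} identifier: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class AssociationMatrix:
    """Binary SM x miRNA association matrix with identifier bookkeeping.

    Rows are small molecules, columns are miRNAs; entry (i, j) is 1 iff
    the association between SM i and miRNA j is experimentally confirmed.
    """

    values: np.ndarray
    sm_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sm_ids = [str(s) for s in self.sm_ids]
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        if self.values.ndim != 2:
            raise ValidationError("association matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("association matrix entries must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.sm_ids), len(self.mirna_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match identifier counts "
                f"({len(self.sm_ids)} SMs, {len(self.mirna_ids)} miRNAs)"
            )
        _check_unique(self.sm_ids, "SM")
        _check_unique(self.mirna_ids, "miRNA")

    @property
    def ns(self) -> int:
        return self.values.shape[0]

    @property
    def nm(self) -> int:
        return self.values.shape[1]

    @property
    def n_known(self) -> int:
        """Number of confirmed associations (1-entries)."""
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """Row/column index pairs of all 1-entries, in row-major order."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), list(self.sm_ids), list(self.mirna_ids))


@dataclasses.dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity set, values in [0, 1]."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = [str(e) for e in self.entity_ids]
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if self.values.shape[0] != len(self.entity_ids):
            raise ValidationError("identifier count does not match matrix dimension")
        _check_unique(self.entity_ids, "entity")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("similarity values must lie in [0, 1]")
        # asymmetry beyond tolerance signals upstream data corruption; never
        # silently symmetrized
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"similarity matrix asymmetric (max |S - S^T| = {asym:.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy reordered to ``ids``, failing loudly on missing identifiers."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise ValidationError(f"identifiers missing from {self.kind or 'similarity'} matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return SimilarityMatrix(self.values[np.ix_(idx, idx)], list(ids), self.kind)


@dataclasses.dataclass
class DatasetBundle:
    """An association matrix plus its SM and miRNA similarity matrices.

    Identifier order is authoritative from the association matrix; all
    similarity matrices are re-indexed to that order on assembly.
    """

    associations: AssociationMatrix
    sm_similarities: list[SimilarityMatrix]
    mirna_similarities: list[SimilarityMatrix]
    name: str = ""

    def __post_init__(self) -> None:
        self.sm_similarities = [s.reindex(self.associations.sm_ids) for s in self.sm_similarities]
        self.mirna_similarities = [s.reindex(self.associations.mirna_ids) for s in self.mirna_similarities]


def read_association_matrix(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a binary association matrix from delimited text.

    First row holds miRNA identifiers, first column SM identifiers; every
    cell must parse as exactly 0 or 1.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no matrix body (header only?)")
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                v = np.nan
            if v not in (0.0, 1.0):
                raise MatrixParseError(
                    f"{path}: non-binary cell {cell!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
                )
            values[i, j] = int(v)
    return AssociationMatrix(values, list(df.index), list(df.columns))


def write_association_matrix(assoc: AssociationMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(assoc.values, index=assoc.sm_ids, columns=assoc.mirna_ids)
    df.to_csv(path, sep=delimiter)


def read_similarity_matrix(path: str | Path, kind: str = "", delimiter: str = "\t") -> SimilarityMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no matrix body (header only?)")
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix(df.to_numpy(dtype=float), list(df.index), kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids)
    df.to_csv(path, sep=delimiter)


def count_unknown(assoc: AssociationMatrix) -> int:
    """Number of unobserved SM-miRNA pairs: ns * nm minus the 1-entries."""
    return assoc.ns * assoc.nm - assoc.n_known
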