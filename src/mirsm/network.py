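"""Heterogeneous-network target matrix: assembly, projection and splitting.

The SM similarity network, the miRNA similarity network and the bipartite
association edges are combined into one heterogeneous network whose
adjacency matrix

    H = [[Ssm, M], [M^T, Sm]]

is the target of matrix completion. The observation set Omega covers both
similarity blocks entirely and, within the association blocks, only the
confirmed (value-1) entries: zeros in M are exactly the entries to be
recovered, so they are treated as missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AssociationMatrix, SimilarityMatrix, ValidationError

__all__ = [
    "TargetMatrix",
    "ScoreMatrix",
    "assemble_target",
    "project",
    "split_result",
    "write_score_matrix",
    "ranked_pairs",
    "write_ranked_pairs",
]

#: slack for entries marginally outside [0, 1] from floating-point roundoff
BOUND_TOL = 1e-9


@dataclasses.dataclass
class TargetMatrix:
    """The (ns+nm) x (ns+nm) adjacency matrix H with its observation mask."""

    values: np.ndarray
    mask: np.ndarray
    ns: int
    nm: int

    def __post_init__(self) -> None:
        n = self.ns + self.nm
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValidationError(f"target matrix and mask must be {n}x{n}")
        if np.abs(self.values - self.values.T).max() > BOUND_TOL:
            raise ValidationError("target matrix H must be symmetric at assembly")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValidationError("observation mask must be symmetric")

    @property
    def n(self) -> int:
        return self.ns + self.nm

    @property
    def association_block(self) -> np.ndarray:
        return self.values[: self.ns, self.ns :]


@dataclasses.dataclass
class ScoreMatrix:
    """ns x nm matrix of association scores in [0, 1]."""

    values: np.ndarray
    sm_ids: list[str]
    mirna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sm_ids), len(self.mirna_ids)):
            raise ValidationError("score matrix shape does not match identifier counts")
        if self.values.size and (
            self.values.min() < -BOUND_TOL or self.values.max() > 1 + BOUND_TOL
        ):
            raise ValidationError("score matrix entries must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


def assemble_target(
    Ssm: SimilarityMatrix, Sm: SimilarityMatrix, assoc: AssociationMatrix
) -> TargetMatrix:
    """Build H = [[Ssm, M], [M^T, Sm]] and its observation mask.

    The mask is 1 on both similarity blocks and on the confirmed association
    entries (and their transposes); unconfirmed (zero) association entries
    are unobserved.
    """
    ns, nm = assoc.ns, assoc.nm
    if Ssm.n != ns:
        raise ValidationError(f"SM similarity is {Ssm.n}x{Ssm.n}, expected {ns}x{ns}")
    if Sm.n != nm:
        raise ValidationError(f"miRNA similarity is {Sm.n}x{Sm.n}, expected {nm}x{nm}")
    if Ssm.entity_ids != assoc.sm_ids or Sm.entity_ids != assoc.mirna_ids:
        raise ValidationError("similarity identifiers do not match association matrix order")
    M = assoc.values.astype(float)
    H = np.block([[Ssm.values, M], [M.T, Sm.values]])
    mask = np.zeros((ns + nm, ns + nm), dtype=np.int8)
    mask[:ns, :ns] = 1
    mask[ns:, ns:] = 1
    mask[:ns, ns:] = assoc.values
    mask[ns:, :ns] = assoc.values.T
    return TargetMatrix(H, mask, ns, nm)


def project(mask: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Orthogonal projection P_Omega: keep observed entries, zero the rest."""
    if mask.shape != X.shape:
        raise ValidationError(f"mask shape {mask.shape} != matrix shape {X.shape}")
    return np.where(mask != 0, X, 0.0)


def split_result(
    H_prime: np.ndarray,
    ns: int,
    nm: int,
    sm_ids: list[str],
    mirna_ids: list[str],
) -> tuple[SimilarityMatrix, ScoreMatrix, SimilarityMatrix]:
    """Split a recovered matrix into (enhanced Ssm', scores M', enhanced Sm').

    The top-right block is the prediction score matrix; the diagonal blocks
    are the enhanced similarity matrices. Scores come from the top-right
    block only; any solver asymmetry between the two association blocks is a
    diagnostic, not averaged away.
    """
    if H_prime.shape != (ns + nm, ns + nm):
        raise ValidationError(f"recovered matrix must be {ns + nm}x{ns + nm}")
    if H_prime.min() < -BOUND_TOL or H_prime.max() > 1 + BOUND_TOL:
        raise ValidationError("recovered matrix entries must lie in [0, 1]")
    Hc = np.clip(H_prime, 0.0, 1.0)
    # the diagonal blocks may pick up tiny asymmetry from the solver; keep
    # them valid SimilarityMatrix instances
    Ssm_p = Hc[:ns, :ns]
    Sm_p = Hc[ns:, ns:]
    Ssm_enh = SimilarityMatrix((Ssm_p + Ssm_p.T) / 2, list(sm_ids), "enhanced-sm")
    Sm_enh = SimilarityMatrix((Sm_p + Sm_p.T) / 2, list(mirna_ids), "enhanced-mirna")
    scores = ScoreMatrix(Hc[:ns, ns:], list(sm_ids), list(mirna_ids))
    return Ssm_enh, scores, Sm_enh


def write_score_matrix(scores: ScoreMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(scores.values, index=scores.sm_ids, columns=scores.mirna_ids)
    df.to_csv(path, sep=delimiter)


def ranked_pairs(scores: ScoreMatrix, known: AssociationMatrix | None = None) -> pd.DataFrame:
    """Long-format table (sm_id, mirna_id, score, known_flag), descending score.

    Ties break deterministically by identifier so repeated runs produce
    byte-identical files.
    """
    ns, nm = scores.values.shape
    sm = np.repeat(scores.sm_ids, nm)
    mi = np.tile(scores.mirna_ids, ns)
    flags = (known.values.ravel() if known is not None else np.zeros(ns * nm, dtype=np.int8))
    df = pd.DataFrame(
        {"sm_id": sm, "mirna_id": mi, "score": scores.values.ravel(), "known_flag": flags}
    )
    return df.sort_values(
        ["score", "sm_id", "mirna_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


def write_ranked_pairs(
    scores: ScoreMatrix,
    path: str | Path,
    known: AssociationMatrix | None = None,
    delimiter: str = "\t",
) -> None:
    ranked_pairs(scores, known).to_csv(path, sep=delimiter, index=False)
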