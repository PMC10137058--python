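"""Weighted-average integration of multiple similarity matrices.

Several similarity measures are typically available for the same entity set
(for small molecules: side-effect, chemical-structure, functional and
indication-phenotype based; for miRNAs: gene-functional and disease-phenotype
based). To reduce the bias of any single measure they are integrated by a
weighted average, S = sum_i w_i S_i / sum_i w_i, with all weights defaulting
to 1. Input matrices must be complete; entities absent from a source must be
resolved upstream.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io import SimilarityMatrix, ValidationError

__all__ = ["FusionWeights", "fuse_similarities"]


@dataclasses.dataclass
class FusionWeights:
    """Positive weights, one per similarity matrix being fused."""

    weights: tuple[float, ...]

    def __init__(self, weights: Sequence[float]):
        ws = tuple(float(w) for w in weights)
        if not ws:
            raise ValidationError("at least one fusion weight required")
        if any(w <= 0 for w in ws):
            raise ValidationError(f"fusion weights must be positive, got {ws}")
        object.__setattr__(self, "weights", ws)


def fuse_similarities(
    matrices: Sequence[SimilarityMatrix],
    weights: FusionWeights | Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Integrate similarity matrices by weighted averaging.

    Parameters
    ----------
    matrices
        One or more similarity matrices over the same entities in the same
        order. A single matrix with weight 1 passes through unchanged.
    weights
        One positive weight per matrix; defaults to all ones.
    """
    if not matrices:
        raise ValidationError("at least one similarity matrix required")
    if weights is None:
        weights = FusionWeights([1.0] * len(matrices))
    elif not isinstance(weights, FusionWeights):
        weights = FusionWeights(weights)
    if len(weights.weights) != len(matrices):
        raise ValidationError(
            f"{len(weights.weights)} weights for {len(matrices)} matrices"
        )
    ids = matrices[0].entity_ids
    for s in matrices[1:]:
        if s.entity_ids != ids:
            raise ValidationError("similarity matrices differ in entities or order")
    w = np.asarray(weights.weights)
    stacked = np.stack([s.values for s in matrices])
    fused = np.tensordot(w, stacked, axes=1) / w.sum()
    # exact symmetry is preserved by the average of symmetric inputs
    kind = "integrated(" + ",".join(s.kind or "?" for s in matrices) + ")"
    return SimilarityMatrix(fused, list(ids), kind)
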