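"""Model/Results interface over the completion pipeline.

``AssociationCompletion`` is constructed from an association matrix plus SM
and miRNA similarity information (single matrices or lists, which are fused
by weighted averaging); ``fit`` assembles the heterogeneous-network target
matrix, runs the truncated-nuclear-norm solver and returns a
``CompletionResults`` carrying the score matrix, the enhanced similarity
matrices, solver diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fusion import FusionWeights, fuse_similarities
from .io import AssociationMatrix, DatasetBundle, SimilarityMatrix
from .network import (
    ScoreMatrix,
    assemble_target,
    ranked_pairs,
    split_result,
    write_ranked_pairs,
    write_score_matrix,
)
from .solver import SolverConfig, SolverState, solve

__all__ = ["AssociationCompletion", "CompletionResults"]


def _as_similarity(
    sim: SimilarityMatrix | Sequence[SimilarityMatrix],
    weights: FusionWeights | Sequence[float] | None,
) -> SimilarityMatrix:
    if isinstance(sim, SimilarityMatrix):
        sim = [sim]
    return fuse_similarities(list(sim), weights)


class AssociationCompletion:
    """Small molecule-miRNA association prediction by matrix completion.

    Parameters
    ----------
    associations
        Binary SM x miRNA association matrix (the training observations).
    sm_similarity, mirna_similarity
        A similarity matrix, or a list of them to be integrated by weighted
        averaging (weights default to 1).
    config
        Solver tunables; defaults follow the standard setting (r=1, three
        outer passes, ADMM cap 300).
    """

    def __init__(
        self,
        associations: AssociationMatrix,
        sm_similarity: SimilarityMatrix | Sequence[SimilarityMatrix],
        mirna_similarity: SimilarityMatrix | Sequence[SimilarityMatrix],
        config: SolverConfig | None = None,
        sm_weights: FusionWeights | Sequence[float] | None = None,
        mirna_weights: FusionWeights | Sequence[float] | None = None,
    ):
        self.associations = associations
        self.sm_similarity = _as_similarity(sm_similarity, sm_weights).reindex(associations.sm_ids)
        self.mirna_similarity = _as_similarity(mirna_similarity, mirna_weights).reindex(
            associations.mirna_ids
        )
        self.config = config if config is not None else SolverConfig()

    @classmethod
    def from_bundle(
        cls,
        bundle: DatasetBundle,
        config: SolverConfig | None = None,
        sm_weights: FusionWeights | Sequence[float] | None = None,
        mirna_weights: FusionWeights | Sequence[float] | None = None,
    ) -> "AssociationCompletion":
        return cls(
            bundle.associations,
            bundle.sm_similarities,
            bundle.mirna_similarities,
            config=config,
            sm_weights=sm_weights,
            mirna_weights=mirna_weights,
        )

    def fit(self) -> "CompletionResults":
        """Run the two-step solver and return the results object."""
        target = assemble_target(self.sm_similarity, self.mirna_similarity, self.associations)
        H_prime, state = solve(target, self.config)
        ssm_enh, scores, sm_enh = split_result(
            H_prime,
            self.associations.ns,
            self.associations.nm,
            self.associations.sm_ids,
            self.associations.mirna_ids,
        )
        return CompletionResults(self, H_prime, state, scores, ssm_enh, sm_enh)


class CompletionResults:
    """Fitted completion: scores, enhanced similarities and diagnostics."""

    def __init__(
        self,
        model: AssociationCompletion,
        H_prime: np.ndarray,
        state: SolverState,
        scores: ScoreMatrix,
        enhanced_sm_similarity: SimilarityMatrix,
        enhanced_mirna_similarity: SimilarityMatrix,
    ):
        self.model = model
        self.H_prime = H_prime
        self.state = state
        self.scores = scores
        self.enhanced_sm_similarity = enhanced_sm_similarity
        self.enhanced_mirna_similarity = enhanced_mirna_similarity

    @property
    def score_values(self) -> np.ndarray:
        return self.scores.values

    @property
    def max_asymmetry(self) -> float:
        """Largest |X - X^T| entry recorded over the outer passes."""
        return max(self.state.asymmetry)

    @property
    def inner_iterations(self) -> list[int]:
        """ADMM iterations used in each outer pass."""
        counts: dict[int, int] = {}
        for rec in self.state.trace:
            counts[int(rec["l"])] = int(rec["k"])
        return [counts[l] for l in sorted(counts)]

    def ranked_pairs(self):
        """All SM-miRNA pairs sorted by descending score, with known flags."""
        return ranked_pairs(self.scores, self.model.associations)

    def write_scores(self, path) -> None:
        write_score_matrix(self.scores, path)

    def write_ranked_pairs(self, path) -> None:
        write_ranked_pairs(self.scores, path, self.model.associations)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of a regression results table."""
        m = self.model
        a = m.associations
        cfg = m.config
        known = a.n_known
        obs = a.values.astype(bool)
        mean_known = float(self.scores.values[obs].mean()) if known else float("nan")
        mean_unknown = float(self.scores.values[~obs].mean())
        lines = [
            "        Association Matrix Completion Results",
            "=" * 56,
            f"SMs:                 {a.ns:>8d}    miRNAs:        {a.nm:>8d}",
            f"Known associations:  {known:>8d}    Unknown pairs: {a.ns * a.nm - known:>8d}",
            f"Truncation rank r:   {cfg.r:>8d}    Outer passes:  {cfg.outer_iterations:>8d}",
            f"alpha: {cfg.alpha:<8g} beta: {cfg.beta:<8g} gamma: {cfg.gamma:<8g}",
            f"Inner iterations/pass: {self.inner_iterations}",
            f"Final d1: {self.state.d1:.3e}    Final d2: {self.state.d2:.3e}",
            f"Max block asymmetry:   {self.max_asymmetry:.3e}",
            f"Mean score (known 1s): {mean_known:.4f}",
            f"Mean score (unknown):  {mean_unknown:.4f}",
            "=" * 56,
        ]
        return "\n".join(lines)
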