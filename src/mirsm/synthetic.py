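"""Synthetic dataset generator with low-rank latent bipartite structure.

The completion method presumes the SM x miRNA association pattern is driven
by a low-rank latent structure and that the similarity matrices reflect the
same latent factors. The generator draws nonnegative factors U (ns x k) and
V (nm x k), takes the scaled product as a latent association-probability
("truth") matrix, samples the binary observed matrix entry-wise from it at
a calibrated global rate, and induces SM/miRNA similarities as cosine
similarities of the U/V rows (optionally perturbed by symmetric noise).
Every draw is fully determined by the seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .io import AssociationMatrix, DatasetBundle, SimilarityMatrix, ValidationError

__all__ = ["SyntheticSpec", "generate", "holdout"]


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    ns, nm : int
        Numbers of small molecules and miRNAs.
    latent_rank : int
        Rank of the latent factor structure.
    density : float
        Target fraction of 1s in the association matrix, in (0, 1).
    similarity_noise : float
        Standard deviation of symmetric Gaussian noise added to the
        similarity matrices (0 gives exact cosine similarities).
    seed : int
        Seed for all randomness.
    """

    ns: int = 120
    nm: int = 120
    latent_rank: int = 2
    density: float = 0.05
    similarity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ns < 2 or self.nm < 2:
            raise ValidationError("ns and nm must be >= 2")
        if self.latent_rank < 1:
            raise ValidationError("latent_rank must be >= 1")
        if not 0 < self.density < 1:
            raise ValidationError("density must lie in (0, 1)")
        if self.similarity_noise < 0:
            raise ValidationError("similarity_noise must be >= 0")


def _cosine_similarity(F: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    Fn = F / norms
    S = Fn @ Fn.T  # nonnegative rows -> entries already in [0, 1]
    if noise > 0:
        N = rng.normal(0.0, noise, S.shape)
        S = S + (N + N.T) / 2
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate(spec: SyntheticSpec) -> tuple[DatasetBundle, np.ndarray]:
    """Draw a synthetic dataset bundle plus its latent truth matrix.

    Returns the bundle (associations + one SM and one miRNA similarity
    matrix) and the ns x nm truth matrix in [0, 1] used for sampling, for
    recovery scoring.
    """
    rng = np.random.default_rng(spec.seed)
    U = rng.uniform(0.0, 1.0, (spec.ns, spec.latent_rank))
    V = rng.uniform(0.0, 1.0, (spec.nm, spec.latent_rank))
    P = U @ V.T
    truth = P / P.max()  # scaled into [0, 1]
    # one global scale calibrates the expected 1-count to density * ns * nm
    scale = spec.density * spec.ns * spec.nm / truth.sum()
    prob = truth * scale
    if prob.max() > 1:
        raise ValidationError(
            f"density {spec.density} infeasible for latent rank {spec.latent_rank}: "
            "required per-entry probability exceeds 1"
        )
    M = (rng.random((spec.ns, spec.nm)) < prob).astype(np.int8)
    sm_ids = [f"SM:{i:04d}" for i in range(spec.ns)]
    mirna_ids = [f"hsa-mir-{j:04d}" for j in range(spec.nm)]
    assoc = AssociationMatrix(M, sm_ids, mirna_ids)
    ssm = SimilarityMatrix(_cosine_similarity(U, spec.similarity_noise, rng), sm_ids, "latent-cosine")
    sm = SimilarityMatrix(_cosine_similarity(V, spec.similarity_noise, rng), mirna_ids, "latent-cosine")
    bundle = DatasetBundle(assoc, [ssm], [sm], name=f"synthetic-seed{spec.seed}")
    return bundle, truth


def holdout(
    assoc: AssociationMatrix, fraction: float, seed: int = 0
) -> tuple[AssociationMatrix, list[tuple[int, int]]]:
    """Remove ceil(fraction * #1s) confirmed associations uniformly at random.

    Returns the reduced training matrix and the held-out (row, col) index
    pairs; setting those entries back to 1 reconstructs the original.
    """
    if not 0 < fraction < 1:
        raise ValidationError("holdout fraction must lie in (0, 1)")
    ones = assoc.known_pairs()
    n_hold = math.ceil(fraction * len(ones))
    if n_hold >= len(ones):
        raise ValidationError("holdout would remove every known association")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ones), size=n_hold, replace=False)
    held = [ones[i] for i in sorted(pick)]
    train = assoc.copy()
    for i, j in held:
        train.values[i, j] = 0
    return train, held
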