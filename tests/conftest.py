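import numpy as np
import pytest

from mirsm import AssociationMatrix, SimilarityMatrix, SolverConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic bundle shared across tests (30 x 24, ~70 ones)."""
    bundle, truth = generate(SyntheticSpec(ns=30, nm=24, latent_rank=2, density=0.1,
                                           similarity_noise=0.05, seed=11))
    return bundle, truth


@pytest.fixture(scope="session")
def fast_config():
    """Solver config with a modest inner cap for quick protocol tests."""
    return SolverConfig(r=2, maxiter=100)


@pytest.fixture()
def toy_assoc():
    """3 x 4 association matrix with 3 known associations."""
    values = np.array([[1, 0, 0, 1], [0, 0, 0, 0], [0, 1, 0, 0]])
    return AssociationMatrix(values, ["s1", "s2", "s3"], ["m1", "m2", "m3", "m4"])


def make_similarity(n, ids=None, seed=0):
    """Random valid similarity matrix with unit diagonal."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0, 1, (n, n))
    S = (raw + raw.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, ids or [f"e{i}" for i in range(n)])
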