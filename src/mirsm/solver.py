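"""Truncated-nuclear-norm matrix completion via a two-step scheme with ADMM.

The completion problem is

    min_X  ||X||_r   s.t.  P_Omega(X) = P_Omega(H),  0 <= X_ij <= 1,

where ||X||_r = sum_{i>r} sigma_i(X) is the truncated nuclear norm: the sum
of all singular values beyond the r largest. Unlike the plain nuclear norm
it leaves the dominant rank-r spectrum unpenalized, giving a tighter
surrogate for the rank function. Writing ||X||_r = ||X||_* - max Tr(A X B^T)
over row-orthonormal A, B turns the problem into a two-step iteration:

  step 1: fix X, take A/B as the top-r left/right singular vectors of X
          (which maximize Tr(A X B^T) at sum of the r largest singular values);
  step 2: fix A, B and solve the convex subproblem in X by ADMM with an
          auxiliary variable W (constrained to [0,1] entry-wise), a nuclear-
          norm variable Z and multiplier Y.

The equality constraint is relaxed into a quadratic penalty weighted by
``alpha`` so that noisy observed entries do not have to be interpolated
exactly. With r = 0 the truncation term vanishes and the scheme reduces to
bounded nuclear-norm completion, a useful differential baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .io import ValidationError
from .network import TargetMatrix, project

__all__ = [
    "SolverConfig",
    "SolverState",
    "SolverError",
    "truncated_nuclear_norm",
    "truncation_factors",
    "update_W",
    "singular_value_shrinkage",
    "update_Z",
    "update_Y",
    "convergence_check",
    "admm_subproblem",
    "solve",
]

logger = logging.getLogger(__name__)

#: recommended truncation ranks; larger r buys little accuracy at higher cost
RECOMMENDED_R = (1, 2, 3)
#: outer-iteration range that suffices in practice
OUTER_RANGE = (1, 4)
#: singular-value gap below which the choice of truncation factors is ill-determined
TIE_TOL = 1e-10


class SolverError(RuntimeError):
    """Numerical failure inside the completion solver."""


@dataclasses.dataclass
class SolverConfig:
    """All tunables of the two-step/ADMM scheme.

    Parameters
    ----------
    r : int
        Truncation rank: the r largest singular values are unpenalized.
        r = 0 disables truncation (plain bounded nuclear-norm completion).
    outer_iterations : int
        Number of two-step (SVD + subproblem) passes.
    maxiter : int
        Inner ADMM iteration cap.
    alpha : float
        Weight of the observation-fit term.
    beta : float
        ADMM penalty parameter (> 0).
    gamma : float
        Multiplier learning rate; the Y step size is gamma * beta.
    eps1, eps2 : float
        Stop tolerances on the relative change of Z and on the change of
        that change.
    warm_start : bool
        If True, inner variables carry over between outer passes instead of
        being re-initialized to P_Omega(H) (experimental; default False).
    """

    r: int = 1
    outer_iterations: int = 3
    maxiter: int = 300
    alpha: float = 1.0
    beta: float = 10.0
    gamma: float = 1.0
    eps1: float = 2e-3
    eps2: float = 1e-5
    warm_start: bool = False

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValidationError("truncation rank r must be >= 0")
        if self.outer_iterations < 1:
            raise ValidationError("outer_iterations must be >= 1")
        if self.maxiter < 1:
            raise ValidationError("maxiter must be >= 1")
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValidationError("eps1 and eps2 must be > 0")
        if not OUTER_RANGE[0] <= self.outer_iterations <= OUTER_RANGE[1]:
            logger.info(
                "outer_iterations=%d outside the usual range %s",
                self.outer_iterations,
                OUTER_RANGE,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolverConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SolverState:
    """Final iterates and the per-iteration trace of a solve."""

    X: np.ndarray
    A: np.ndarray
    B: np.ndarray
    W: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    d1: float
    d2: float
    trace: list[dict[str, float]]
    #: max |X - X^T| recorded after each outer pass
    asymmetry: list[float]

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)


def truncated_nuclear_norm(X: np.ndarray, r: int) -> float:
    """Sum of all singular values of X beyond the r largest."""
    if r < 0 or r > min(X.shape):
        raise ValidationError(f"r={r} out of range for shape {X.shape}")
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[r:].sum())


def truncation_factors(X: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-r singular-vector factors A (r x n) and B (r x n) of X.

    A holds the first r left singular vectors transposed, B the first r
    right singular vectors transposed, taken from a single decomposition so
    the sign ambiguity of singular vectors cancels in A^T B. Then
    Tr(A X B^T) = sum of the r largest singular values.
    """
    if r < 0 or r > min(X.shape):
        raise ValidationError(f"r={r} out of range for shape {X.shape}")
    U, s, Vt = np.linalg.svd(X)
    if 0 < r < len(s) and s[r - 1] - s[r] < TIE_TOL:
        logger.warning(
            "singular values sigma_%d and sigma_%d nearly tied (gap %.3g); "
            "truncation factors are ill-determined",
            r,
            r + 1,
            s[r - 1] - s[r],
        )
    return U[:, :r].T, Vt[:r, :]


def update_W(
    Z: np.ndarray,
    Y: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    mask: np.ndarray,
    H: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """One W-step: closed-form minimizer of the Lagrangian in W, clipped to [0,1].

    The unconstrained minimizer is
    T - alpha/(alpha+beta) * P_Omega(T) with
    T = Y/beta + (alpha/beta) P_Omega(H) + A^T B / beta + Z, after which
    entries are clipped entry-wise into [0, 1].
    """
    T = Y / beta + (alpha / beta) * project(mask, H) + (A.T @ B) / beta + Z
    W_bar = T - (alpha / (alpha + beta)) * project(mask, T)
    return np.clip(W_bar, 0.0, 1.0)


def singular_value_shrinkage(L: np.ndarray, tau: float) -> np.ndarray:
    """Soft-threshold the singular values of L by tau (proximal operator of
    the nuclear norm): U diag(max(0, sigma_i - tau)) V^T."""
    if tau < 0:
        raise ValidationError("shrinkage threshold must be >= 0")
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    s_shr = np.maximum(s - tau, 0.0)
    keep = s_shr > 0
    return (U[:, keep] * s_shr[keep]) @ Vt[keep, :]


def update_Z(W: np.ndarray, Y: np.ndarray, beta: float) -> np.ndarray:
    """One Z-step: shrink (W - Y/beta) at threshold 1/beta."""
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    return singular_value_shrinkage(W - Y / beta, 1.0 / beta)


def update_Y(Y: np.ndarray, Z: np.ndarray, W: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """One multiplier step (gradient ascent): Y + gamma * beta * (Z - W)."""
    return Y + gamma * beta * (Z - W)


def convergence_check(
    Z_new: np.ndarray,
    Z_old: np.ndarray,
    d1_old: float,
    eps1: float,
    eps2: float,
) -> tuple[float, float, bool]:
    """Stop statistics for the inner loop.

    d1 is the relative Frobenius change of Z; d2 the change of d1 relative
    to max(d1_old, 1). The loop stops when both fall below their
    tolerances.
    """
    denom = np.linalg.norm(Z_old)
    if denom == 0:
        d1 = float(np.linalg.norm(Z_new))
        logger.warning("||Z_old||_F = 0 in convergence check; using absolute norm")
    else:
        d1 = float(np.linalg.norm(Z_new - Z_old) / denom)
    d2 = abs(d1 - d1_old) / max(d1_old, 1.0)
    return d1, d2, bool(d1 <= eps1 and d2 <= eps2)


def admm_subproblem(
    A: np.ndarray,
    B: np.ndarray,
    target: TargetMatrix,
    config: SolverConfig,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    outer_index: int = 0,
    trace: list[dict[str, float]] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray], float, float]:
    """Solve the convex subproblem at fixed truncation factors by ADMM.

    Iterates W -> Z -> Y updates until the stop conditions fire or the
    iteration cap is reached; the final W is the next outer iterate. Returns
    (X_next, (W, Z, Y), d1, d2).
    """
    H, mask = target.values, target.mask
    if init is None:
        PH = project(mask, H)
        W, Z, Y = PH.copy(), PH.copy(), PH.copy()
    else:
        W, Z, Y = init
    d1_old = 1.0  # undefined at k=1; conservative so the loop never stops there
    d1 = d2 = float("nan")
    for k in range(1, config.maxiter + 1):
        W = update_W(Z, Y, A, B, mask, H, config.alpha, config.beta)
        Z_new = update_Z(W, Y, config.beta)
        Y = update_Y(Y, Z_new, W, config.gamma, config.beta)
        if not (np.isfinite(W).all() and np.isfinite(Z_new).all() and np.isfinite(Y).all()):
            raise SolverError(f"non-finite values at outer pass {outer_index}, inner iteration {k}")
        d1, d2, stop = convergence_check(Z_new, Z, d1_old, config.eps1, config.eps2)
        Z = Z_new
        d1_old = d1
        if trace is not None:
            trace.append({"l": outer_index, "k": k, "d1": d1, "d2": d2})
        if stop and k >= 2:
            break
    return W, (W, Z, Y), d1, d2


def solve(target: TargetMatrix, config: SolverConfig | None = None) -> tuple[np.ndarray, SolverState]:
    """Complete the target matrix by the two-step scheme.

    X is initialized to P_Omega(H). Each outer pass decomposes the current
    iterate to refresh the truncation factors, then runs the ADMM subproblem
    (inner variables re-initialized to P_Omega(H) unless warm-starting).
    Returns the final iterate, entry-wise in [0, 1], plus the solver state
    with the full trace. The solver is deterministic given its inputs.
    """
    if config is None:
        config = SolverConfig()
    n = target.n
    if config.r > n:
        raise ValidationError(f"truncation rank r={config.r} exceeds matrix dimension {n}")
    X = project(target.mask, target.values)
    trace: list[dict[str, float]] = []
    asymmetry: list[float] = []
    inner = None
    A = B = np.zeros((0, n))
    d1 = d2 = float("nan")
    for l in range(1, config.outer_iterations + 1):
        A, B = truncation_factors(X, config.r)
        init = inner if (config.warm_start and inner is not None) else None
        X, inner, d1, d2 = admm_subproblem(
            A, B, target, config, init=init, outer_index=l, trace=trace
        )
        asymmetry.append(float(np.abs(X - X.T).max()))
    W, Z, Y = inner
    return X, SolverState(X=X, A=A, B=B, W=W, Z=Z, Y=Y, d1=d1, d2=d2, trace=trace, asymmetry=asymmetry)
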