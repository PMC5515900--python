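"""Robust principal component analysis by principal component pursuit.

Solves the convex program

    min_{L,S}  ||L||_* + lambda * ||S||_1   s.t.  X = L + S

splitting a feature matrix X into a low-rank part L (regular background
activity) and a sparse part S (deviant, here emotion-related, events).
The solver is the inexact augmented Lagrange multiplier (ALM) method:
alternate a singular-value-thresholding step for L and an elementwise
soft-thresholding step for S against a growing penalty.

Two lambda rules are provided.  ``paper`` uses 1/max(m, n); ``sqrt``
uses 1/sqrt(max(m, n)), the scaling under which exact recovery of
incoherent low-rank plus sparse matrices is guaranteed.  Both are
first-class; the decomposition quality of the two rules can differ
substantially, so results are worth reporting for each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RpcaResult",
    "soft_threshold",
    "singular_value_threshold",
    "default_lambda",
    "rpca_decompose",
    "numerical_support",
]


def numerical_support(S: np.ndarray, rel_tol: float = 1e-4) -> np.ndarray:
    """Boolean support of a sparse matrix up to numerical zero.

    A convex solver drives non-support entries toward zero but may
    leave residue at the accuracy of the final iterate, so support is
    declared where ``|S|`` exceeds ``rel_tol`` times the largest entry
    magnitude (an all-zero matrix has empty support).
    """
    S = np.asarray(S)
    top = np.abs(S).max()
    if top == 0:
        return np.zeros(S.shape, dtype=bool)
    return np.abs(S) > rel_tol * top


@dataclass
class RpcaResult:
    """Decomposition X ~ L + S with solver diagnostics."""

    L: np.ndarray
    S: np.ndarray
    lam: float
    iterations: int
    residual: float  # ||X - L - S||_F / ||X||_F
    converged: bool
    #: Per-iteration feasible-completion objective
    #: ||L_k||_* + lam*(||S_k||_1 + ||X - L_k - S_k||_1), i.e. the objective of
    #: the feasible point (L_k, S_k + Z_k).  ALM iterates themselves are
    #: infeasible and their raw objective approaches the optimum from below;
    #: the feasible completion is the quantity that decreases monotonically.
    objective_history: list[float] = field(default_factory=list)

    @property
    def nuclear_norm(self) -> float:
        return float(np.linalg.svd(self.L, compute_uv=False).sum())

    @property
    def l1_norm(self) -> float:
        return float(np.abs(self.S).sum())

    @property
    def objective(self) -> float:
        return self.nuclear_norm + self.lam * self.l1_norm


def soft_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise sign(m) * max(|m| - tau, 0): proximal map of tau*||.||_1."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def singular_value_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Soft-threshold the singular values of M: proximal map of tau*||.||_*."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    U, s, Vt = np.linalg.svd(np.asarray(M, dtype=float), full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def default_lambda(m: int, n: int, rule: str = "paper") -> float:
    """Sparsity weight for an m x n problem under the named rule."""
    if m < 1 or n < 1:
        raise ValueError("matrix dimensions must be positive")
    if rule == "paper":
        return 1.0 / max(m, n)
    if rule == "sqrt":
        return 1.0 / np.sqrt(max(m, n))
    raise ValueError(f"unknown lambda rule {rule!r}")


def rpca_decompose(
    X: np.ndarray,
    lam: float | None = None,
    lambda_rule: str = "paper",
    tol: float = 1e-7,
    max_iter: int = 1000,
    mu: float | None = None,
    rho: float = 1.5,
    progress_tol: float = 1e-2,
) -> RpcaResult:
    """Decompose X into low-rank L and sparse S by inexact ALM.

    Parameters
    ----------
    X : array (m, n)
        Finite input matrix (a MESH feature matrix, typically 110 x 73).
    lam : float, optional
        Sparsity weight; defaults to ``default_lambda(m, n, lambda_rule)``.
    tol : float
        Convergence threshold on ||X - L - S||_F / ||X||_F.
    mu : float, optional
        Initial penalty; defaults to 1.25 / ||X||_2.
    rho : float
        Penalty growth factor.
    progress_tol : float
        The penalty grows only once the S-step has settled at the
        current penalty level (mu * ||S_k - S_{k-1}||_F / ||X||_F on
        the unit-spectral-norm scale below this threshold); growing it
        unconditionally stalls the iterate short of the optimum on
        harder problems.

    The matrix is normalized to unit spectral norm internally and the
    decomposition rescaled on return, so the result is exactly
    equivariant under X -> cX.  Non-convergence within ``max_iter`` is reported via
    ``converged=False``, not an exception.
    """
    values = getattr(X, "values", X)
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    m, n = X.shape
    if lam is None:
        lam = default_lambda(m, n, lambda_rule)
    if lam <= 0:
        raise ValueError("lambda must be positive")

    norm_x = np.linalg.norm(X, "fro")
    if norm_x == 0:
        return RpcaResult(
            L=np.zeros_like(X), S=np.zeros_like(X), lam=lam,
            iterations=1, residual=0.0, converged=True, objective_history=[0.0],
        )

    spectral = np.linalg.norm(X, 2)
    Xn = X / spectral  # unit spectral norm; rescaled on return
    norm_xn = np.linalg.norm(Xn, "fro")
    mu = 1.25 if mu is None else mu * spectral
    mu_max = mu * 1e7
    # Dual-variable scaling of Lin et al.'s inexact ALM.
    Y = Xn / max(1.0, np.abs(Xn).max() / lam)
    L = np.zeros_like(Xn)
    S = np.zeros_like(Xn)
    history: list[float] = []
    converged = False
    it = 0
    residual = 1.0
    for it in range(1, max_iter + 1):
        L = singular_value_threshold(Xn - S + Y / mu, 1.0 / mu)
        S_prev = S
        S = soft_threshold(Xn - L + Y / mu, lam / mu)
        Z = Xn - L - S
        Y = Y + mu * Z
        if mu * np.linalg.norm(S - S_prev, "fro") / norm_xn < progress_tol:
            mu = min(mu * rho, mu_max)
        residual = np.linalg.norm(Z, "fro") / norm_xn
        history.append(
            float(spectral * (
                np.linalg.svd(L, compute_uv=False).sum()
                + lam * (np.abs(S).sum() + np.abs(Z).sum())
            ))
        )
        if residual < tol:
            converged = True
            break
    return RpcaResult(
        L=spectral * L, S=spectral * S, lam=float(lam), iterations=it,
        residual=float(residual), converged=converged, objective_history=history,
    )
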