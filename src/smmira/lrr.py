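"""Low-rank representation denoising of the association matrix.

The known association matrix A (small molecules x miRNAs) is modeled as
``A = A X + E`` where X is a low-rank self-representation coefficient
matrix and E collects column-sparse gross noise:

    min_{X,E}  ||X||_*  +  alpha ||E||_{2,1}    s.t.  A = A X + E

The problem is solved by inexact augmented Lagrange multipliers (IALM):
alternating closed-form proximal updates for an auxiliary nuclear-norm
variable J (singular value thresholding), for X (a penalized least squares
with the cached factorization of I + A^T A), and for E (column-wise L2,1
shrinkage), followed by multiplier updates and a geometric increase of the
penalty mu.  The denoised association matrix is ``A* = A X*``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_io import AssociationData

logger = logging.getLogger("smmira")


@dataclass
class IALMConfig:
    """Solver settings: balance alpha, penalty schedule (mu0, rho, mu_max), stopping."""

    alpha: float = 0.1
    mu0: float = 1e-4
    mu_max: float = 1e10
    rho: float = 1.1
    tol: float = 1e-7
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.mu0 <= 0 or self.tol <= 0:
            raise ValueError("alpha, mu0 and tol must be positive")
        if self.mu0 >= self.mu_max:
            raise ValueError("mu0 must be below mu_max")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class LRRResult:
    X: np.ndarray                 # coefficient matrix (square)
    E: np.ndarray                 # sparse noise, same shape as A
    A_star: np.ndarray            # denoised associations, same shape as A
    n_iter: int
    residuals: list[tuple[float, float]]  # (||A-AX-E||_inf, ||X-J||_inf) per iteration
    converged: bool
    sm_ids: list[str] | None = field(default=None)
    mirna_ids: list[str] | None = field(default=None)


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: prox of ``tau ||.||_*`` at M.

    Returns ``U shrink(Sigma, tau) V^T`` where shrink subtracts tau from each
    singular value and floors at zero.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if M.size == 0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def l21_shrink(M: np.ndarray, tau: float) -> np.ndarray:
    """Column-wise L2,1 shrinkage: prox of ``tau ||.||_{2,1}`` at M.

    Column j is scaled by ``max(0, 1 - tau/||M_j||_2)``; columns with norm
    at most tau (including zero columns) become zero.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    norms = np.linalg.norm(M, axis=0)
    scale = np.zeros_like(norms)
    np.divide(norms - tau, norms, out=scale, where=norms > tau)
    return M * scale


def ialm_solve(A: np.ndarray, cfg: IALMConfig | None = None) -> LRRResult:
    """Solve the low-rank representation program for A by IALM.

    The coefficient matrix X is square with the column dimension of A
    (``A = A X + E``).  Iterates until both infinity-norm residuals
    ``||A - AX - E||_inf`` and ``||X - J||_inf`` drop below ``cfg.tol`` or
    ``cfg.max_iter`` is reached; non-convergence yields a warning and a
    result flagged ``converged=False``, never an exception.
    """
    cfg = cfg or IALMConfig()
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("A must be non-empty")
    n = A.shape[1]

    X = np.zeros((n, n))
    J = np.zeros((n, n))
    E = np.zeros_like(A)
    Y1 = np.zeros_like(A)
    Y2 = np.zeros((n, n))
    mu = cfg.mu0

    AtA = A.T @ A
    factor = cho_factor(np.eye(n) + AtA)

    residuals: list[tuple[float, float]] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        J = svt(X + Y2 / mu, 1.0 / mu)
        X = cho_solve(factor, AtA - A.T @ E + J + (A.T @ Y1 - Y2) / mu)
        E = l21_shrink(A - A @ X + Y1 / mu, cfg.alpha / mu)
        R1 = A - A @ X - E
        R2 = X - J
        Y1 = Y1 + mu * R1
        Y2 = Y2 + mu * R2
        mu = min(cfg.rho * mu, cfg.mu_max)
        r1 = float(np.abs(R1).max()) if R1.size else 0.0
        r2 = float(np.abs(R2).max())
        residuals.append((r1, r2))
        if r1 < cfg.tol and r2 < cfg.tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "IALM did not converge in %d iterations (residuals %.3e, %.3e)",
            cfg.max_iter, *residuals[-1])
    return LRRResult(X=X, E=E, A_star=A @ X, n_iter=it,
                     residuals=residuals, converged=converged)


def denoise_associations(data: AssociationData, cfg: IALMConfig | None = None,
                         side: str = "mirna") -> LRRResult:
    """Denoise an association dataset: ``A* = A X*`` with A in SM x miRNA orientation.

    ``side`` selects which self-representation is learned: ``"mirna"``
    (default) factors A through a miRNA x miRNA coefficient matrix;
    ``"sm"`` factors A^T through an SM x SM one (A* is re-transposed so its
    orientation never changes).
    """
    if side not in ("mirna", "sm"):
        raise ValueError(f"unknown side {side!r}")
    if side == "mirna":
        res = ialm_solve(data.A, cfg)
    else:
        res = ialm_solve(data.A.T, cfg)
        res = LRRResult(X=res.X, E=res.E.T, A_star=res.A_star.T, n_iter=res.n_iter,
                        residuals=res.residuals, converged=res.converged)
    res.sm_ids = list(data.sm_ids)
    res.mirna_ids = list(data.mirna_ids)
    return res
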