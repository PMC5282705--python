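"""Principal Component Pursuit via augmented Lagrange multipliers.

Decomposes an observed matrix ``D`` into a low-rank background ``L`` plus a
sparse perturbation ``S`` by solving the convex program

    minimize   ||L||_* + lam * ||S||_1
    subject to D = L + S,

where ``||.||_*`` is the nuclear norm (sum of singular values) and ``||.||_1``
the elementwise l1 norm. The solver is the (inexact) augmented-Lagrangian
iteration: each outer step applies singular-value thresholding to update L,
elementwise soft thresholding to update S, and then a gradient-ascent update
of the multiplier ``Y <- Y + mu (D - L - S)``. An exact variant repeats the
L/S alternation to convergence before each multiplier update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "SolverConfig",
    "PCPSolution",
    "soft_threshold",
    "soft_threshold_matrix",
    "singular_value_threshold",
    "update_sparse",
    "update_lowrank",
    "update_multiplier",
    "default_lambda",
    "solve_pcp",
    "solver_trace",
]

#: singular values above this fraction of sigma_1 count toward rank_L
RANK_FLOOR = 1e-8
#: cap on mu growth, as a multiple of the initial mu
MU_MAX_FACTOR = 1e7


def default_lambda(shape: tuple[int, int]) -> float:
    """Sparsity weight ``1/sqrt(max(p, N))`` from exact-recovery theory."""
    return 1.0 / np.sqrt(max(shape))


@dataclass(frozen=True)
class SolverConfig:
    """Parameters of the augmented-Lagrangian PCP solver.

    Attributes
    ----------
    lam
        Sparsity weight; ``None`` selects ``1/sqrt(max(p, N))``.
    mu0
        Initial penalty parameter; ``None`` selects ``1.25 / sigma_1(D)``.
    rho
        Multiplicative growth of mu per outer iteration (>= 1).
    tol
        Stopping threshold on the relative feasibility residual
        ``||D - L - S||_F / ||D||_F``.
    max_iter
        Outer-iteration cap; reaching it reports ``converged=False``.
    scheme
        ``"inexact_single_update"`` (one L and one S update per multiplier
        step) or ``"exact_inner_loop"`` (alternate L/S to inner convergence
        before each multiplier step).
    trace
        Record per-iteration residual / rank / sparsity diagnostics.
    """

    lam: float | None = None
    mu0: float | None = None
    rho: float = 1.5
    tol: float = 1e-7
    max_iter: int = 1000
    scheme: str = "inexact_single_update"
    trace: bool = False
    inner_tol_factor: float = 1e-6
    max_inner: int = 100

    def __post_init__(self) -> None:
        if self.lam is not None and not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.mu0 is not None and not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if not self.rho >= 1:
            raise ValueError(f"rho must be >= 1, got {self.rho}")
        if not self.tol > 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.scheme not in ("inexact_single_update", "exact_inner_loop"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass(frozen=True)
class PCPSolution:
    """Recovered components and diagnostics of one PCP solve."""

    L: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    iterations: int
    converged: bool
    final_residual: float
    rank_L: int
    nnz_S: int
    lam: float
    mu_final: float
    trace: tuple[tuple[int, float, int, int], ...] = field(default=())


def soft_threshold(x: float, tau: float) -> float:
    """Scalar shrinkage ``sgn(x) * max(|x| - tau, 0)``."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    return float(np.sign(x) * max(abs(x) - tau, 0.0))


def soft_threshold_matrix(X: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage; the proximal operator of ``tau * ||.||_1``."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    X = np.asarray(X, dtype=float)
    return np.sign(X) * np.maximum(np.abs(X) - tau, 0.0)


def singular_value_threshold(X: np.ndarray, tau: float) -> np.ndarray:
    """Shrink the singular values of ``X`` by ``tau``.

    Computes a thin SVD ``X = U diag(sigma) V^T`` and returns
    ``U diag(max(sigma - tau, 0)) V^T`` — the proximal operator of
    ``tau * ||.||_*``. Only the components with ``sigma > tau`` are
    remultiplied.
    """
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in input to SVT")
    U, sigma, Vt = scipy.linalg.svd(X, full_matrices=False, lapack_driver="gesdd")
    keep = sigma > tau
    if not np.any(keep):
        return np.zeros_like(X)
    return (U[:, keep] * (sigma[keep] - tau)) @ Vt[keep, :]


def _check_shapes(*mats: np.ndarray) -> None:
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch among operands: {sorted(shapes)}")


def update_sparse(
    D: np.ndarray, L: np.ndarray, Y: np.ndarray, lam: float, mu: float
) -> np.ndarray:
    """Closed-form S-minimizer of the augmented Lagrangian (L, Y fixed)."""
    D, L, Y = (np.asarray(a, dtype=float) for a in (D, L, Y))
    _check_shapes(D, L, Y)
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return soft_threshold_matrix(D - L + Y / mu, lam / mu)


def update_lowrank(
    D: np.ndarray, S: np.ndarray, Y: np.ndarray, mu: float
) -> np.ndarray:
    """Closed-form L-minimizer of the augmented Lagrangian (S, Y fixed)."""
    D, S, Y = (np.asarray(a, dtype=float) for a in (D, S, Y))
    _check_shapes(D, S, Y)
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return singular_value_threshold(D - S + Y / mu, 1.0 / mu)


def update_multiplier(
    Y: np.ndarray, D: np.ndarray, L: np.ndarray, S: np.ndarray, mu: float
) -> np.ndarray:
    """Dual ascent step ``Y + mu (D - L - S)``."""
    Y, D, L, S = (np.asarray(a, dtype=float) for a in (Y, D, L, S))
    _check_shapes(Y, D, L, S)
    return Y + mu * (D - L - S)


def _rank_above_floor(L: np.ndarray) -> int:
    sigma = scipy.linalg.svdvals(L)
    if sigma.size == 0 or sigma[0] == 0:
        return 0
    return int(np.count_nonzero(sigma > RANK_FLOOR * sigma[0]))


def solve_pcp(D: np.ndarray, config: SolverConfig | None = None) -> PCPSolution:
    """Recover low-rank ``L`` and sparse ``S`` with ``D = L + S``.

    Parameters
    ----------
    D
        Observed matrix, finite entries.
    config
        Solver parameters; defaults are suitable for matrices whose low-rank
        part satisfies the usual incoherence conditions.

    Returns
    -------
    PCPSolution
        With ``converged=True`` when the relative feasibility residual
        dropped below ``config.tol`` within ``config.max_iter`` outer
        iterations; otherwise ``converged=False`` with diagnostics (no
        exception is raised for non-convergence).
    """
    if config is None:
        config = SolverConfig()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValueError(f"D must be 2-D, got ndim={D.ndim}")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite entries in D")

    lam = config.lam if config.lam is not None else default_lambda(D.shape)
    d_fro = float(np.linalg.norm(D, "fro"))
    d_spectral = float(scipy.linalg.svdvals(D)[0]) if d_fro > 0 else 0.0

    if config.mu0 is not None:
        mu = config.mu0
    elif d_spectral > 0:
        mu = 1.25 / d_spectral
    else:
        mu = 1.25
    mu_max = mu * MU_MAX_FACTOR

    # dual-feasible warm start Y0 = D / max(||D||_2, ||D||_inf / lam)
    dual_scale = max(d_spectral, float(np.abs(D).max(initial=0.0)) / lam)
    Y = D / dual_scale if dual_scale > 0 else np.zeros_like(D)
    L = np.zeros_like(D)
    S = np.zeros_like(D)

    denom = d_fro if d_fro > 0 else 1.0  # absolute residual for D = 0
    inner_tol = config.inner_tol_factor * denom

    trace: list[tuple[int, float, int, int]] = []
    converged = False
    residual = float(np.linalg.norm(D - L - S, "fro")) / denom
    iterations = 0

    for k in range(1, config.max_iter + 1):
        iterations = k
        S_outer_prev = S
        if config.scheme == "inexact_single_update":
            L = update_lowrank(D, S, Y, mu)
            S = update_sparse(D, L, Y, lam, mu)
        else:  # exact_inner_loop
            for _ in range(config.max_inner):
                L = update_lowrank(D, S, Y, mu)
                S_new = update_sparse(D, L, Y, lam, mu)
                change = float(np.linalg.norm(S_new - S, "fro"))
                S = S_new
                if change <= inner_tol:
                    break
        Y = update_multiplier(Y, D, L, S, mu)
        residual = float(np.linalg.norm(D - L - S, "fro")) / denom
        if config.trace:
            trace.append(
                (k, residual, _rank_above_floor(L), int(np.count_nonzero(S)))
            )
        if residual <= config.tol:
            if config.scheme == "inexact_single_update":
                converged = True
                break
            # feasibility alone is a weak certificate for the exact scheme
            # (the sub-problem may still be moving); also require the outer
            # S iterate to have settled
            s_change = float(np.linalg.norm(S - S_outer_prev, "fro")) / denom
            if s_change <= config.tol:
                converged = True
                break
        mu = min(config.rho * mu, mu_max)

    return PCPSolution(
        L=L,
        S=S,
        Y=Y,
        iterations=iterations,
        converged=converged,
        final_residual=residual,
        rank_L=_rank_above_floor(L),
        nnz_S=int(np.count_nonzero(S)),
        lam=lam,
        mu_final=mu,
        trace=tuple(trace),
    )


def solver_trace(solution: PCPSolution):
    """Per-iteration diagnostics as a pandas DataFrame.

    Columns: ``iteration``, ``residual``, ``rank_L``, ``nnz_S`` — one row per
    outer iteration. Empty when the solve ran with ``trace=False``.
    """
    import pandas as pd

    return pd.DataFrame(
        list(solution.trace), columns=["iteration", "residual", "rank_L", "nnz_S"]
    )
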