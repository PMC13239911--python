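"""ADMM solver for the AFTV-regularised nonnegative low-rank representation.

The model learns an n x n nonnegative coefficient matrix R expressing every
cell as a combination of all cells,

    min_R  1/2 ||X - X R||_F^2 + alpha ||R||_*
           + lambda_tv ||X R||_AFTV      s.t.  R >= 0,

where ||.||_* is the nuclear norm (convex surrogate for rank) and the AFTV
term is the adaptive fractional-order total variation of the reconstruction
X R (see :mod:`aftvlrr.fractional`).  Splitting R = Q decouples the nuclear
norm; the augmented Lagrangian

    L = 1/2 ||X - XR||_F^2 + alpha ||Q||_* + lambda_tv ||XR||_AFTV
        + <Y, Q - R> + 1/(2 mu) ||Q - R||_F^2

is minimised by alternating updates.  Note the 1/mu penalty convention
(large mu = weak penalty); the multiplier step is Y <- Y + (R - Q)/mu.

Per iteration:

* R-step — stationarity of L in R with the AFTV gradient lagged at the
  previous reconstruction X R^l (lagged-diffusivity) gives the SPD system
  ``(X'X + I/mu) R = X'X - Y + Q/mu - lambda_tv X' G``, solved with one
  cached Cholesky factorisation, then projected onto R >= 0.
* Q-step — singular value thresholding of ``R + mu Y`` at level alpha*mu
  (the exact nuclear-norm proximal scaling), then projected onto Q >= 0.
* Y-step — dual ascent ``Y <- Y + (R - Q)/mu``.

The multiplier enters the R/Q steps with the sign that makes the Y-step an
ascent on the dual (the textbook ADMM layout for the coupling <Y, R - Q>).

The learnt coefficients are symmetrised into the cell-cell similarity
``S = (R + R')/2`` that feeds spectral clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .fractional import AFTVParams, aftv_energy, aftv_gradient

logger = logging.getLogger("aftvlrr")

__all__ = [
    "SolverParams",
    "ADMMState",
    "SimilarityMatrix",
    "svt",
    "update_R",
    "update_Q",
    "update_Y",
    "objective",
    "build_similarity",
    "fit_aftv_lrr",
]


@dataclass
class SolverParams:
    """Hyperparameters of the ADMM solver.

    alpha : nuclear-norm weight (low-rankness strength), default 0.5.
    mu : augmented-Lagrangian penalty in the 1/mu convention, default 1.0.
    aftv : fractional-TV settings (order beta, truncation K, weight
        lambda_tv); ``lambda_tv = 0`` reduces the model to plain nonnegative
        LRR.
    tol : relative stopping tolerance on ||R^{l+1} - R^l||_F.
    max_iter : iteration cap.
    relative_stop : divide the change by 1 + ||R^l||_F (scale-robust); set
        False for the absolute rule.
    project_q : nonnegative projection of Q after thresholding (breaks exact
        prox optimality but keeps the similarity nonnegative end to end).
    seed : recorded for reproducibility; the solver itself is deterministic.
    """

    alpha: float = 0.5
    mu: float = 1.0
    aftv: AFTVParams = field(default_factory=AFTVParams)
    tol: float = 1e-5
    max_iter: int = 100
    relative_stop: bool = True
    project_q: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ADMMState:
    """Iterates and convergence traces of one solver run."""

    R: np.ndarray
    Q: np.ndarray
    Y: np.ndarray
    iteration: int = 0
    converged: bool = False
    objective_trace: list[float] = field(default_factory=list)
    primal_residual_trace: list[float] = field(default_factory=list)
    dual_residual_trace: list[float] = field(default_factory=list)
    change_trace: list[float] = field(default_factory=list)

    def trace_frame(self):
        """Convergence traces as a DataFrame (iteration, objective, residuals)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.iteration + 1),
                "objective": self.objective_trace,
                "primal_residual": self.primal_residual_trace,
                "dual_residual": self.dual_residual_trace,
                "change": self.change_trace,
            }
        )


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative cell-cell affinity ``S = (R + R')/2``."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("similarity matrix must be square")


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding — the nuclear-norm proximal operator.

    Returns ``U soft(Sigma, tau) V'`` where the singular values are reduced
    by ``tau`` and floored at zero.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite input to svt")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def factorize_normal_matrix(X: np.ndarray, mu: float):
    """Cholesky factorisation of ``X'X + I/mu`` (SPD), cached across iterations."""
    n = X.shape[1]
    return cho_factor(X.T @ X + np.eye(n) / mu)


def update_R(
    state: ADMMState,
    X: np.ndarray,
    params: SolverParams,
    cached_factorization,
) -> np.ndarray:
    """R-step: solve the lagged-AFTV stationarity system, project onto R >= 0."""
    XtX = X.T @ X
    rhs = XtX - state.Y + state.Q / params.mu
    lam = params.aftv.lambda_tv
    if lam > 0:
        G = aftv_gradient(X @ state.R, params.aftv)
        rhs = rhs - lam * (X.T @ G)
    R = cho_solve(cached_factorization, rhs)
    return np.maximum(R, 0.0)


def update_Q(state: ADMMState, params: SolverParams) -> np.ndarray:
    """Q-step: SVT of ``R + mu Y`` at threshold alpha*mu, optional projection."""
    Q = svt(state.R + params.mu * state.Y, params.alpha * params.mu)
    if params.project_q:
        Q = np.maximum(Q, 0.0)
    return Q


def update_Y(state: ADMMState, params: SolverParams) -> np.ndarray:
    """Dual ascent ``Y <- Y + (R - Q)/mu``."""
    return state.Y + (state.R - state.Q) / params.mu


def objective(X: np.ndarray, R: np.ndarray, params: SolverParams) -> float:
    """Model objective 1/2||X-XR||_F^2 + alpha||R||_* + lambda_tv AFTV(XR)."""
    fid = 0.5 * np.linalg.norm(X - X @ R) ** 2
    nuc = params.alpha * np.linalg.svd(R, compute_uv=False).sum()
    lam = params.aftv.lambda_tv
    tv = lam * aftv_energy(X @ R, params.aftv.operator) if lam > 0 else 0.0
    return float(fid + nuc + tv)


def build_similarity(R: np.ndarray) -> SimilarityMatrix:
    """Symmetrise the learnt coefficients: ``S = (R + R')/2``."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("coefficient matrix must be square")
    return SimilarityMatrix(0.5 * (R + R.T))


def fit_aftv_lrr(
    X: np.ndarray, params: SolverParams | None = None
) -> tuple[ADMMState, SimilarityMatrix]:
    """Run the full ADMM loop on a preprocessed genes x cells matrix X.

    Initialises R = Q = Y = 0 and iterates the R/Q/Y updates, recording the
    objective, primal residual ``||R - Q||_F``, dual residual
    ``||Q^{l+1} - Q^l||_F / mu`` and successive change ``||R^{l+1} - R^l||_F``
    each iteration.  Stops when the (relative) change drops below ``tol`` or
    ``max_iter`` is reached; non-convergence is flagged, not fatal.
    """
    params = params or SolverParams()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input matrix")
    n = X.shape[1]
    state = ADMMState(R=np.zeros((n, n)), Q=np.zeros((n, n)), Y=np.zeros((n, n)))
    fac = factorize_normal_matrix(X, params.mu)

    for it in range(params.max_iter):
        R_old = state.R
        Q_old = state.Q
        R_new = update_R(state, X, params, fac)
        state.R = R_new
        Q_new = update_Q(state, params)
        state.Q = Q_new
        state.Y = update_Y(state, params)
        state.iteration = it + 1

        obj = objective(X, state.R, params)
        change = float(np.linalg.norm(R_new - R_old))
        state.objective_trace.append(obj)
        state.primal_residual_trace.append(float(np.linalg.norm(R_new - Q_new)))
        state.dual_residual_trace.append(
            float(np.linalg.norm(Q_new - Q_old)) / params.mu
        )
        state.change_trace.append(change)

        if not np.isfinite(obj):
            raise FloatingPointError(
                f"objective diverged at iteration {it + 1}; last finite value "
                f"{state.objective_trace[-2] if it else 'none'} — consider a "
                "smaller mu or lambda_tv"
            )
        denom = 1.0 + float(np.linalg.norm(R_old)) if params.relative_stop else 1.0
        if change / denom < params.tol:
            state.converged = True
            break

    if not state.converged:
        logger.warning(
            "ADMM hit max_iter=%d without meeting tol=%g (last change %.3g)",
            params.max_iter,
            params.tol,
            state.change_trace[-1],
        )
    return state, build_similarity(state.R)
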