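"""Solvers for the generalized-L1 (fused LASSO) regression.

The objective is

    f(b) = ||Y - X b||_2^2 + lambda1 ||D1 b||_1 + lambda2 ||D2 b||_1

with D1 the diagonal weight penalty and D2 the fusion-difference rows.  The
production path is local quadratic approximation (LQA): each |u| is
majorized by a quadratic around the previous iterate (u^2 + eps smoothing),
so every step solves a ridge-like normal equation by Cholesky; the
eps-smoothed objective is non-increasing across iterations by the MM
argument.  An independent ADMM solver for the same convex program serves as
a test oracle on small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .design import StackedRegression

__all__ = [
    "SolverOptions",
    "FitResult",
    "objective",
    "fit_lqa",
    "fit_oracle",
    "cross_validate",
]


@dataclass
class SolverOptions:
    """Numerical constants for the LQA iteration."""

    lqa_epsilon: float = 1e-8
    max_iterations: int = 500
    tolerance: float = 1e-8     # convergence threshold on max |beta change|
    # LQA parks exact zeros at ~sqrt(lqa_epsilon), up to a few times that
    # near the selection boundary; report anything below as absent (standardized
    # coefficients of real edges sit orders of magnitude above this)
    zero_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.lqa_epsilon <= 0 or self.tolerance <= 0:
            raise ValueError("lqa_epsilon and tolerance must be positive")
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be non-negative")


@dataclass
class FitResult:
    """A fitted coefficient vector with its provenance."""

    beta: np.ndarray
    lambda1: float
    lambda2: float
    objective: float
    iterations: int
    converged: bool
    cv_errors: np.ndarray | None = None      # grid of CV MSE, or None
    lambda1_grid: tuple[float, ...] | None = None
    lambda2_grid: tuple[float, ...] | None = None
    response_id: str | None = None
    smoothed_path: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def objective(
    beta: np.ndarray, sr: StackedRegression, lambda1: float, lambda2: float
) -> float:
    """Evaluate ||Y - X b||^2 + lambda1 ||D1 b||_1 + lambda2 ||D2 b||_1."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (sr.X.shape[1],):
        raise ValueError(f"beta has shape {beta.shape}, expected ({sr.X.shape[1]},)")
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty parameters must be >= 0")
    resid = sr.Y - sr.X @ beta
    val = float(resid @ resid)
    val += lambda1 * float(np.abs(sr.d1 * beta).sum())
    if sr.D2.size:
        val += lambda2 * float(np.abs(sr.D2 @ beta).sum())
    return val


def _ridge_init(XtX: np.ndarray, XtY: np.ndarray) -> np.ndarray:
    p = XtX.shape[0]
    ridge = 1e-3 * np.trace(XtX) / p + 1e-12
    return np.linalg.solve(XtX + ridge * np.eye(p), XtY)


def _chol_solve(M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(M, lower=True, check_finite=False), rhs,
                         check_finite=False)
    except LinAlgError:
        jitter = 1e-10 * (np.trace(M) / M.shape[0] + 1.0)
        return cho_solve(
            cho_factor(M + jitter * np.eye(M.shape[0]), lower=True,
                       check_finite=False),
            rhs, check_finite=False,
        )


def _lqa_core(
    XtX: np.ndarray,
    XtY: np.ndarray,
    YtY: float,
    d1: np.ndarray,
    D2: np.ndarray,
    lambda1: float,
    lambda2: float,
    opts: SolverOptions,
) -> tuple[np.ndarray, int, bool, np.ndarray]:
    """LQA iteration on precomputed cross-products; returns raw (unthresholded)
    beta, iteration count, convergence flag and the smoothed-objective path."""
    eps = opts.lqa_epsilon
    d1sq = d1 * d1
    has_fusion = D2.size > 0
    beta = _ridge_init(XtX, XtY)

    def smoothed(b: np.ndarray) -> float:
        val = YtY - 2.0 * float(XtY @ b) + float(b @ XtX @ b)
        val += lambda1 * float(np.sqrt((d1 * b) ** 2 + eps).sum())
        if has_fusion:
            val += lambda2 * float(np.sqrt((D2 @ b) ** 2 + eps).sum())
        return val

    path = [smoothed(beta)]
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        a1 = 1.0 / np.sqrt((d1 * beta) ** 2 + eps)
        M = XtX + np.diag(0.5 * lambda1 * d1sq * a1)
        if has_fusion:
            a2 = 1.0 / np.sqrt((D2 @ beta) ** 2 + eps)
            M = M + 0.5 * lambda2 * (D2.T * a2) @ D2
        beta_new = _chol_solve(M, XtY)
        path.append(smoothed(beta_new))
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < opts.tolerance:
            converged = True
            break
    return beta, it, converged, np.asarray(path)


def fit_lqa(
    sr: StackedRegression,
    lambda1: float,
    lambda2: float,
    opts: SolverOptions | None = None,
) -> FitResult:
    """Solve the fused-LASSO objective by local quadratic approximation.

    Coefficients with magnitude below ``opts.zero_threshold`` are reported
    as exact zeros; the returned objective is evaluated at the reported
    (thresholded) coefficients.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty parameters must be >= 0")
    opts = opts or SolverOptions()
    XtX = sr.X.T @ sr.X
    XtY = sr.X.T @ sr.Y
    YtY = float(sr.Y @ sr.Y)
    beta, it, converged, path = _lqa_core(
        XtX, XtY, YtY, sr.d1, sr.D2, lambda1, lambda2, opts
    )
    beta = np.where(np.abs(beta) < opts.zero_threshold, 0.0, beta)
    return FitResult(
        beta=beta,
        lambda1=lambda1,
        lambda2=lambda2,
        objective=objective(beta, sr, lambda1, lambda2),
        iterations=it,
        converged=converged,
        response_id=sr.response_id,
        smoothed_path=path,
    )


# ---------------------------------------------------------------------------
# independent convex oracle (ADMM on the generalized lasso)
# ---------------------------------------------------------------------------

_ORACLE_MAX_COLS = 48
_ORACLE_MAX_ROWS = 400


def fit_oracle(
    sr: StackedRegression,
    lambda1: float,
    lambda2: float,
    max_iterations: int = 100_000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Reference solution of the same convex program by ADMM (small instances).

    Splits the penalty as g(z) = sum_r gamma_r |z_r| with z = D b, where D
    stacks the D1 and D2 rows and gamma_r is lambda1 or lambda2.  Entirely
    independent of the LQA path; used as the test oracle.
    """
    p = sr.X.shape[1]
    if p > _ORACLE_MAX_COLS or sr.X.shape[0] > _ORACLE_MAX_ROWS:
        raise ValueError(
            f"oracle size guard exceeded ({sr.X.shape}); it is a test oracle "
            "for small instances only"
        )
    D_rows = [np.diag(sr.d1)]
    gammas = [np.full(p, lambda1)]
    if sr.D2.size:
        D_rows.append(sr.D2)
        gammas.append(np.full(sr.D2.shape[0], lambda2))
    D = np.vstack(D_rows)
    gamma = np.concatenate(gammas)

    XtX2 = 2.0 * sr.X.T @ sr.X
    XtY2 = 2.0 * sr.X.T @ sr.Y
    DtD = D.T @ D
    rho = 1.0
    z = np.zeros(D.shape[0])
    u = np.zeros(D.shape[0])
    beta = np.zeros(p)
    factor = cho_factor(XtX2 + rho * DtD + 1e-12 * np.eye(p), lower=True)
    for _ in range(max_iterations):
        beta = cho_solve(factor, XtY2 + rho * D.T @ (z - u))
        Db = D @ beta
        z_new = np.sign(Db + u) * np.maximum(np.abs(Db + u) - gamma / rho, 0.0)
        dual_resid = rho * np.linalg.norm(D.T @ (z_new - z))
        z = z_new
        primal = Db - z
        u = u + primal
        primal_resid = np.linalg.norm(primal)
        scale = 1.0 + np.linalg.norm(beta)
        if primal_resid < tol * scale and dual_resid < tol * scale:
            break
        # residual balancing keeps both residuals converging
        if primal_resid > 10.0 * dual_resid and rho < 1e6:
            rho *= 2.0
            u /= 2.0
            factor = cho_factor(XtX2 + rho * DtD + 1e-12 * np.eye(p), lower=True)
        elif dual_resid > 10.0 * primal_resid and rho > 1e-6:
            rho /= 2.0
            u *= 2.0
            factor = cho_factor(XtX2 + rho * DtD + 1e-12 * np.eye(p), lower=True)
    return beta


# ---------------------------------------------------------------------------
# cross-validation over the (lambda1, lambda2) grid
# ---------------------------------------------------------------------------


def _fold_assignment(
    sr: StackedRegression, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign every row to a fold, stratified by condition block."""
    if folds > min(sr.n_per_condition):
        raise ValueError(
            f"{folds} folds cannot each sample every condition "
            f"(smallest block has {min(sr.n_per_condition)} rows); lower cv_folds"
        )
    assignment = np.empty(sr.n_rows, dtype=int)
    for sl in sr.condition_row_slices():
        idx = np.arange(sl.start, sl.stop)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def cross_validate(
    sr: StackedRegression,
    lambda1_grid,
    lambda2_grid,
    folds: int = 10,
    seed: int = 0,
    opts: SolverOptions | None = None,
) -> FitResult:
    """Select (lambda1, lambda2) by k-fold CV and refit on all rows.

    Folds are stratified by condition so that every fold (hence every
    training split) samples every condition block.  The CV score is the
    mean held-out squared prediction error; ties are broken toward the
    larger lambda1 + lambda2 (then larger lambda1), i.e. toward the
    sparser, more fused model.
    """
    lambda1_grid = tuple(float(v) for v in lambda1_grid)
    lambda2_grid = tuple(float(v) for v in lambda2_grid)
    if not lambda1_grid or not lambda2_grid:
        raise ValueError("lambda grids must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    opts = opts or SolverOptions()
    rng = np.random.default_rng(seed)
    assignment = _fold_assignment(sr, folds, rng)

    # fold fits only rank (lambda1, lambda2) pairs; a looser beta tolerance
    # is enough there, while the final refit uses the full opts precision
    fold_opts = SolverOptions(
        lqa_epsilon=opts.lqa_epsilon,
        max_iterations=opts.max_iterations,
        tolerance=max(opts.tolerance, 1e-6),
        zero_threshold=opts.zero_threshold,
    )
    XtX_full = sr.X.T @ sr.X
    XtY_full = sr.X.T @ sr.Y
    sq_err = np.zeros((folds, len(lambda1_grid), len(lambda2_grid)))
    n_test = np.zeros(folds)
    n_unconverged = 0
    for f in range(folds):
        test = assignment == f
        X_test, Y_test = sr.X[test], sr.Y[test]
        XtX = XtX_full - X_test.T @ X_test
        XtY = XtY_full - X_test.T @ Y_test
        Y_train = sr.Y[~test]
        YtY = float(Y_train @ Y_train)
        n_test[f] = int(test.sum())
        for a, l1 in enumerate(lambda1_grid):
            for b, l2 in enumerate(lambda2_grid):
                beta, _, converged, _ = _lqa_core(
                    XtX, XtY, YtY, sr.d1, sr.D2, l1, l2, fold_opts
                )
                n_unconverged += not converged
                resid = Y_test - X_test @ beta
                sq_err[f, a, b] = float(resid @ resid)
    if n_unconverged:
        warnings.warn(
            f"LQA hit the iteration cap in {n_unconverged} of "
            f"{folds * len(lambda1_grid) * len(lambda2_grid)} CV fits",
            stacklevel=2,
        )
    cv_errors = (sq_err / n_test[:, None, None]).mean(axis=0)

    best = np.min(cv_errors)
    candidates = [
        (lambda1_grid[a] + lambda2_grid[b], lambda1_grid[a], a, b)
        for a in range(len(lambda1_grid))
        for b in range(len(lambda2_grid))
        if cv_errors[a, b] <= best * (1.0 + 1e-12)
    ]
    _, _, a_best, b_best = max(candidates)
    l1, l2 = lambda1_grid[a_best], lambda2_grid[b_best]

    result = fit_lqa(sr, l1, l2, opts)
    result.cv_errors = cv_errors
    result.lambda1_grid = lambda1_grid
    result.lambda2_grid = lambda2_grid
    return result
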