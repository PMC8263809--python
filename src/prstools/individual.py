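"""Individual-level model fitting.

Variational-Bayes ridge/Bolt/BayesR with a 90/10 cross-validated prior
grid, and a penalized-lasso coordinate-descent path with warm starts,
per-SNP penalty factors proportional to 1/sqrt(e_j), a gradient-bound
strong-set screen and ten-fold cross-validation for early stopping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .formats import GenotypeMatrix, Phenotype
from .megaprs import _prior_arrays, default_grid
from .vb import PriorSpec

logger = logging.getLogger(__name__)


@dataclass
class VbFit:
    beta: np.ndarray
    converged: bool
    iterations: int


@dataclass
class CvResult:
    """Grid candidates, their validation MSEs, and the full-data winner."""

    grid: list
    mse: np.ndarray
    winner: int
    beta: np.ndarray

    def __post_init__(self) -> None:
        if self.mse[self.winner] != self.mse.min():
            raise ValueError("winner must attain the minimal validation MSE")


def _as_xy(G, Y):
    X = G.standardized() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    y = Y.values if isinstance(Y, Phenotype) else np.asarray(Y, float)
    if X.shape[0] != len(y):
        raise ValueError("genotype / phenotype length mismatch")
    # column-major: the kernels sweep one SNP column at a time
    return np.asfortranarray(X, dtype=np.float64), y


def vb_fit_individual(G, Y, e_j: np.ndarray, spec: PriorSpec,
                      sigma2_e: float | None = None, tol: float = 1e-6,
                      max_iter: int = 200, lasso_mode: bool = True,
                      checkpoint_path=None,
                      checkpoint_every: int = 10) -> VbFit:
    """Cyclic conditional-posterior updates on individual-level data.

    Each sweep replaces every beta_j with its conditional posterior mean
    (posterior mode for the lasso when ``lasso_mode``), maintaining an
    exact residual vector; iteration stops when the estimated genetic
    variance and residual variance both move by less than ``tol``.

    If ``checkpoint_path`` is given, the current effects are saved every
    ``checkpoint_every`` iterations and an interrupted fit resumes from
    the last save-point.
    """
    X, y = _as_xy(G, Y)
    e_j = np.asarray(e_j, dtype=float)
    if sigma2_e is None:
        sigma2_e = max(1.0 - float(e_j.sum()), 0.05)
    if sigma2_e <= 0:
        raise ValueError("residual variance must be positive")
    weights, variances, rates, use_laplace = _prior_arrays(spec, e_j)

    beta0 = np.zeros(X.shape[1])
    done = 0
    if checkpoint_path is not None:
        from pathlib import Path

        checkpoint_path = Path(checkpoint_path)
        if checkpoint_path.exists():
            ckpt = np.load(checkpoint_path)
            beta0 = ckpt["beta"]
            done = int(ckpt["iterations"])
            logger.info("resuming from checkpoint at iteration %d", done)

    def run(b0, iters):
        return _kernels.vb_individual_kernel(
            X, y, weights, variances, rates, use_laplace,
            bool(lasso_mode), float(sigma2_e), tol, iters, b0,
        )

    if checkpoint_path is None:
        beta, converged, iters = run(beta0, max_iter)
        total = iters
    else:
        beta, converged, total = beta0, 0, done
        while total < max_iter and not converged:
            chunk = min(checkpoint_every, max_iter - total)
            beta, converged, iters = run(beta, chunk)
            total += iters
            np.savez(checkpoint_path, beta=beta, iterations=total)
    if not converged:
        warnings.warn(
            f"variational fit not converged after {max_iter} iterations; "
            "returning best iterate", stacklevel=2,
        )
    return VbFit(beta=beta, converged=bool(converged), iterations=total)


def cv_select(G, Y, e_j: np.ndarray, tool: str,
              grid: list | None = None, split: float = 0.9,
              seed: int = 0, **fit_kwargs) -> CvResult:
    """Pick prior parameters by a seeded 90/10 validation split.

    Every candidate is fitted on the training split; validation MSE on the
    held-out split ranks them (ties to the earliest grid position); the
    winner is refitted on all samples.
    """
    X, y = _as_xy(G, Y)
    grid = grid if grid is not None else default_grid(tool)
    if not grid:
        raise ValueError("empty prior grid")
    n = len(y)
    n_train = int(round(split * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError("too few samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, va = perm[:n_train], perm[n_train:]
    # re-standardize the training split so the contract X_j^T X_j = n holds
    Xtr = X[tr]
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    ytr = y[tr]
    ytr = (ytr - ytr.mean()) / ytr.std()
    Xva = (X[va] - mu) / sd
    mses = np.empty(len(grid))
    for i, spec in enumerate(grid):
        fit = vb_fit_individual(Xtr, ytr, e_j, spec, **fit_kwargs)
        pred = Xva @ fit.beta
        mses[i] = float(np.mean((y[va] - pred) ** 2))
    winner = int(np.argmin(mses))
    final = vb_fit_individual(X, y, e_j, grid[winner], **fit_kwargs)
    return CvResult(grid=list(grid), mse=mses, winner=winner,
                    beta=final.beta)


# ---------------------------------------------------------------------------
# penalized lasso path


@dataclass
class LassoPath:
    lambdas: np.ndarray
    betas: np.ndarray            # (n_lambda, m)
    cv_error: np.ndarray
    stop_index: int              # chosen lambda (minimal CV error)

    @property
    def beta(self) -> np.ndarray:
        return self.betas[self.stop_index]


def _cd_solve_path(X, y, pf, lambdas, tol, max_sweeps):
    """Warm-started coordinate descent down a lambda path with a
    sequential-strong-rule screen and KKT verification."""
    n, m = X.shape
    beta = np.zeros(m)
    resid = y.copy()
    betas = np.empty((len(lambdas), m))
    lam_prev = lambdas[0]
    for k, lam in enumerate(lambdas):
        grad = _kernels.gradient_abs(X, resid)
        strong = grad >= pf * (2.0 * lam - lam_prev)
        active = np.where(strong | (beta != 0))[0].astype(np.int64)
        while True:
            if len(active):
                _kernels.lasso_cd_active(
                    X, resid, beta, active, pf, lam, tol, max_sweeps
                )
            grad = _kernels.gradient_abs(X, resid)
            violations = np.where((grad > lam * pf + 1e-9) & (beta == 0))[0]
            if len(violations) == 0:
                break
            active = np.unique(np.concatenate([active, violations]))
        betas[k] = beta
        lam_prev = lam
    return betas


def lasso_path_cd(G, Y, penalty_factors: np.ndarray | None = None,
                  e_j: np.ndarray | None = None,
                  lambdas: np.ndarray | None = None,
                  n_lambda: int = 50, lambda_min_ratio: float = 0.01,
                  folds: int = 10, seed: int = 0, tol: float = 1e-7,
                  max_sweeps: int = 1000, patience: int = 3) -> LassoPath:
    """Penalized lasso with warm starts and CV-based early stopping.

    Minimises 1/(2n) ||Y - X beta||^2 + lam sum_j pf_j |beta_j| with
    pf_j proportional to 1/sqrt(e_j) (normalised to mean 1). The path
    starts at the smallest lambda with an all-zero solution and descends
    geometrically; it stops once the ``folds``-fold CV error has risen for
    ``patience`` consecutive steps. The returned stop index minimises CV
    error over the explored path.
    """
    X, y = _as_xy(G, Y)
    n, m = X.shape
    if penalty_factors is None:
        if e_j is None:
            pf = np.ones(m)
        else:
            pf = 1.0 / np.sqrt(np.asarray(e_j, dtype=float))
    else:
        pf = np.asarray(penalty_factors, dtype=float).copy()
    if np.any(pf <= 0):
        raise ValueError("penalty factors must be positive")
    pf = pf / pf.mean()
    if lambdas is None:
        lam0 = float(np.max(np.abs(X.T @ y) / (n * pf)))
        lambdas = lam0 * lambda_min_ratio ** (
            np.arange(n_lambda) / (n_lambda - 1)
        )
    else:
        lambdas = np.asarray(lambdas, dtype=float)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=np.int64)
    for f in range(folds):
        fold_id[perm[f::folds]] = f
    fold_data = []
    for f in range(folds):
        tr = fold_id != f
        ytr = y[tr]
        if ytr.std() == 0:
            raise ValueError(f"fold {f} has a constant phenotype")
        fold_data.append((np.ascontiguousarray(X[tr]), ytr, X[~tr], y[~tr]))

    # explore the path with CV, stopping early once the error keeps rising
    fold_state = [
        (np.zeros(m), fd[1].copy()) for fd in fold_data
    ]
    cv_err = []
    rising = 0
    lam_prev = lambdas[0]
    explored = 0
    for k, lam in enumerate(lambdas):
        errs = 0.0
        wsum = 0
        for f in range(folds):
            Xtr, ytr, Xva, yva = fold_data[f]
            beta_f, resid_f = fold_state[f]
            grad = _kernels.gradient_abs(Xtr, resid_f)
            strong = grad >= pf * (2.0 * lam - lam_prev)
            active = np.where(strong | (beta_f != 0))[0].astype(np.int64)
            while True:
                if len(active):
                    _kernels.lasso_cd_active(
                        Xtr, resid_f, beta_f, active, pf, lam, tol, max_sweeps
                    )
                grad = _kernels.gradient_abs(Xtr, resid_f)
                viol = np.where((grad > lam * pf + 1e-9) & (beta_f == 0))[0]
                if len(viol) == 0:
                    break
                active = np.unique(np.concatenate([active, viol]))
            pred = Xva @ beta_f
            errs += float(((yva - pred) ** 2).sum())
            wsum += len(yva)
        cv_err.append(errs / wsum)
        explored = k + 1
        lam_prev = lam
        if k > 0 and cv_err[k] > cv_err[k - 1]:
            rising += 1
            if rising >= patience:
                break
        else:
            rising = 0

    lambdas = lambdas[:explored]
    cv_err_arr = np.asarray(cv_err)
    betas = _cd_solve_path(X, y.copy(), pf, lambdas, tol, max_sweeps)
    stop = int(np.argmin(cv_err_arr))
    return LassoPath(lambdas=lambdas, betas=betas, cv_error=cv_err_arr,
                     stop_index=stop)
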