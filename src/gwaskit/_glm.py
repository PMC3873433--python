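"""Small weighted-least-squares GLM core used by the per-SNP scans.

A genome scan makes tens of thousands of small regressions, so the
logistic fits are done with a compact Newton-Raphson (IRLS) loop on
plain numpy arrays. Separation and non-convergence are reported as
flags rather than exceptions so a scan can note a degenerate SNP and
move on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit


@dataclass
class FitResult:
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool
    separation: bool
    n: int

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))


def _logit_llf(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    ``X`` must include any intercept column. Separation is flagged when
    coefficients run away (|beta| > 15 on standardized-scale data is far
    outside any plausible per-allele log-odds) or the Hessian becomes
    numerically singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()
    if start is None:
        ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = np.log(ybar / (1 - ybar)) if np.allclose(X[:, 0], 1.0) else 0.0

    llf = _logit_llf(y, X @ beta)
    converged = False
    singular = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step halving keeps the likelihood monotone
        new_llf = -np.inf
        for _half in range(30):
            cand = beta + step
            new_llf = _logit_llf(y, X @ cand)
            if new_llf >= llf - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if abs(new_llf - llf) < tol * (abs(llf) + 1.0):
            llf = new_llf
            converged = True
            break
        llf = new_llf

    eta = X @ beta
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        singular = True
        cov = np.full((k, k), np.nan)
        bse = np.full(k, np.nan)

    separation = singular or (not converged) or bool(np.max(np.abs(beta)) > 15.0)
    return FitResult(beta, bse, cov, llf, converged and not singular, separation, n)


def fit_ols(X: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares with classical (homoskedastic) covariance."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    XtX = X.T @ X
    try:
        cov = sigma2 * np.linalg.inv(XtX)
        bse = np.sqrt(np.diag(cov))
        singular = rank < k
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        bse = np.full(k, np.nan)
        singular = True
    # Gaussian log-likelihood at the MLE variance (n, not n-k, denominator)
    s2_ml = max(float(resid @ resid) / n, 1e-300)
    llf = -0.5 * n * (np.log(2 * np.pi * s2_ml) + 1.0)
    return FitResult(beta, bse, cov, llf, not singular, singular, n)


def check_full_rank(columns: dict[str, np.ndarray], with_intercept: bool = True) -> None:
    """Raise ValueError naming the first column that is collinear with
    the columns before it (the intercept counts as the first column)."""
    n = len(next(iter(columns.values())))
    mats: list[np.ndarray] = [np.ones((n, 1))] if with_intercept else []
    for name, col in columns.items():
        prev_rank = np.linalg.matrix_rank(np.column_stack(mats)) if mats else 0
        cand = np.column_stack(mats + [np.asarray(col, dtype=float).reshape(-1, 1)])
        if np.linalg.matrix_rank(cand) == prev_rank:
            raise ValueError(
                f"covariate column '{name}' is collinear with preceding columns"
            )
        mats.append(np.asarray(col, dtype=float).reshape(-1, 1))
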