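"""Small, fast logistic-regression fitters shared by the interim and final
analyses.

Three entry points:

* :func:`fit_ml` — Newton-Raphson maximum likelihood with convergence and
  divergence diagnostics (divergence signals separation).
* :func:`fit_firth` — Firth bias-reduced logistic regression (Jeffreys
  penalty via the hat-matrix diagonal), which yields finite estimates under
  separation and empty cells.
* :func:`fit_map` — posterior mode and curvature under box constraints plus
  optional independent normal priors on selected coefficients, used by the
  Laplace approximation at interim analyses.

Design matrices here are tiny (a few hundred rows, 16 columns), so dense
Newton solves are both the simplest and the fastest option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit


@dataclass
class LogisticFitResult:
    coef: np.ndarray
    cov: np.ndarray  # inverse Fisher information at the estimate
    converged: bool
    method: str
    n_iter: int


def _fisher_info(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    w = p * (1.0 - p)
    return (X * w[:, None]).T @ X


def fit_ml(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-8,
    divergence_bound: float = 12.0,
) -> LogisticFitResult:
    """Newton-Raphson ML logistic fit.

    ``converged`` is False when the score does not vanish within
    ``max_iter`` steps, when the information matrix becomes numerically
    singular, or when any coefficient escapes ``divergence_bound`` (the
    footprint of complete or quasi-complete separation).
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (y - p)
        info = _fisher_info(X, p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return LogisticFitResult(beta, np.full((k, k), np.nan), False, "ml", it)
        # dampen overshooting steps early on
        nstep = np.max(np.abs(step))
        if nstep > 5.0:
            step *= 5.0 / nstep
        beta = beta + step
        if np.max(np.abs(beta)) > divergence_bound:
            return LogisticFitResult(beta, np.full((k, k), np.nan), False, "ml", it)
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    info = _fisher_info(X, p)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return LogisticFitResult(beta, cov, converged, "ml", it)


def _firth_penalised_loglik(X, y, beta, ridge):
    eta = X @ beta
    ll = y @ eta - np.sum(np.logaddexp(0.0, eta))
    p = expit(eta)
    info = _fisher_info(X, p) + ridge
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 80,
    tol: float = 1e-6,
) -> LogisticFitResult:
    """Firth bias-reduced logistic regression.

    Solves the modified score equation ``X'(y - p + h (1/2 - p)) = 0`` where
    ``h`` is the diagonal of the hat matrix; estimates are finite under
    separation.  Newton steps are halved until the Jeffreys-penalised
    log-likelihood does not decrease, which prevents the period-two
    oscillation plain Newton can fall into on near-separated data.  The
    reported covariance is the inverse Fisher information at the penalised
    estimate (standard Wald practice for Firth fits).
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    ridge = 1e-10 * np.eye(k)
    pll = _firth_penalised_loglik(X, y, beta, ridge)
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info + ridge)
        except np.linalg.LinAlgError:
            return LogisticFitResult(beta, np.full((k, k), np.nan), False, "firth", it)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        nstep = np.max(np.abs(step))
        if nstep > 5.0:
            step *= 5.0 / nstep
        # step-halving line search on the penalised log-likelihood
        for _ in range(12):
            cand = beta + step
            pll_new = _firth_penalised_loglik(X, y, cand, ridge)
            if pll_new >= pll - 1e-12:
                break
            step = 0.5 * step
        beta = beta + step
        pll = pll_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    p = expit(X @ beta)
    info = _fisher_info(X, p)
    try:
        cov = np.linalg.inv(info + ridge)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return LogisticFitResult(beta, cov, converged, "firth", it)


@dataclass
class MapFitResult:
    mode: np.ndarray
    cov: np.ndarray  # inverse curvature of the negative log-posterior
    at_bound: np.ndarray  # bool mask of coefficients pinned at the prior box
    ridge_used: float
    converged: bool


def fit_map(
    X: np.ndarray,
    y: np.ndarray,
    prior_mean: np.ndarray,
    prior_precision: np.ndarray,
    box_low: float,
    box_high: float,
    curvature_floor: float | None = None,
) -> MapFitResult:
    """Posterior mode of a logistic model with flat box priors everywhere and
    independent normal priors (given by ``prior_precision`` > 0 entries) on a
    subset of coefficients.

    The covariance is the inverse of (Fisher information + prior precision)
    at the mode.  ``curvature_floor`` (default: the precision of a Gaussian
    moment-matched to the uniform box prior, i.e. 12 / width^2) is added to
    the diagonal so that directions the data leave flat get a finite spread
    comparable to the box prior instead of a singular curvature; a ridge is
    escalated tenfold on top if the matrix is still not positive definite.
    The floor enters the curvature only, never the objective.
    """
    k = X.shape[1]
    prior_mean = np.asarray(prior_mean, dtype=float)
    prec = np.asarray(prior_precision, dtype=float)
    if curvature_floor is None:
        curvature_floor = 12.0 / (box_high - box_low) ** 2

    def negpost(b):
        eta = X @ b
        # -loglik, numerically stable via logaddexp
        nll = np.sum(np.logaddexp(0.0, eta)) - y @ eta
        pen = 0.5 * np.sum(prec * (b - prior_mean) ** 2)
        p = expit(eta)
        grad = -(X.T @ (y - p)) + prec * (b - prior_mean)
        return nll + pen, grad

    x0 = np.where(prec > 0, prior_mean, 0.0)
    res = optimize.minimize(
        negpost, x0, jac=True, method="L-BFGS-B",
        bounds=[(box_low, box_high)] * k,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    mode = res.x
    at_bound = (mode <= box_low + 1e-9) | (mode >= box_high - 1e-9)
    p = expit(X @ mode)
    ident = np.eye(k)
    curv = _fisher_info(X, p) + np.diag(prec) + curvature_floor * ident
    ridge = 0.0
    for _ in range(12):
        try:
            np.linalg.cholesky(curv + ridge * ident)
            cov = np.linalg.inv(curv + ridge * ident)
            break
        except np.linalg.LinAlgError:
            ridge = 1e-4 if ridge == 0.0 else ridge * 10.0
    else:  # pragma: no cover - pathological
        cov = np.linalg.pinv(curv)
    return MapFitResult(mode, cov, at_bound, ridge, bool(res.success))
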