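"""Weighted L1/elastic-net penalized logistic regression at one location.

This is the inner optimization of the geographically weighted logistic
lasso: each calibration location fits a logistic model on all observations,
weighted by the spatial kernel, with an L1 (optionally elastic-net) penalty
on the slopes.  The objective minimized is

    f(b0, b) = sum_j wt_j * l(y_j, b0 + x_j.b)
               + lam * (alpha * |b|_1 + (1 - alpha)/2 * |b|_2^2)

where l(y, eta) = log(1 + exp(eta)) - y*eta is the Bernoulli negative
log-likelihood and wt are the kernel weights normalized to sum to one.
Normalizing by the total weight gives lambda a location-independent scale:
the effective kernel mass varies across calibration points, so on the raw
weighted-sum scale the same lambda would penalize dense and sparse
neighbourhoods differently.  The intercept b0 is never penalized.

The solver is cyclic coordinate descent on the iteratively reweighted
least-squares (IRLS) quadratic approximation, warm-started along a
decreasing lambda path — the standard algorithm for penalized GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .exceptions import InputError, ParameterError

# coefficients below this magnitude after convergence are snapped to exact 0
ZERO_SNAP = 1e-10
# IRLS variance floor, guards z-step blowup near mu in {0, 1}
VAR_FLOOR = 1e-5
# clip for probabilities entering logs / logits
PROB_CLIP = 1e-10


@dataclass
class LocalFit:
    """Penalized weighted logistic fit at a single calibration location."""

    intercept: float
    beta: np.ndarray
    lam: float
    alpha: float
    converged: bool
    n_iter: int
    objective: float
    degenerate: bool = False

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def coef(self) -> np.ndarray:
        """Length p+1 vector: intercept followed by slopes."""
        return np.concatenate(([self.intercept], self.beta))


def _check_design(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be 2-D")
    n, p = X.shape
    if y.shape != (n,) or w.shape != (n,):
        raise InputError(f"shape mismatch: X {X.shape}, y {y.shape}, w {w.shape}")
    if not (np.isfinite(X).all() and np.isfinite(y).all() and np.isfinite(w).all()):
        raise InputError("design contains non-finite values")
    if (w < 0).any():
        raise InputError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ParameterError("total weight must be positive")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("y must be binary in {0, 1}")
    return X, y, w


def objective_value(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    intercept: float,
    beta: np.ndarray,
    lam: float,
    alpha: float,
) -> float:
    """Weight-normalized penalized negative log-likelihood at (intercept, beta)."""
    wt = w / w.sum()
    eta = intercept + X @ beta
    nll = float(wt @ (np.logaddexp(0.0, eta) - y * eta))
    pen = lam * (alpha * np.abs(beta).sum() + 0.5 * (1.0 - alpha) * float(beta @ beta))
    return nll + pen


def lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Smallest lasso penalty at which all slopes are zero.

    At the all-zero-slope solution the intercept is the weighted logit of
    the outcome mean, so the score of slope k is the weighted covariance
    between x_k and y; the KKT conditions give

        lambda_max = max_k | sum_j wt_j x_jk (y_j - ybar_w) |

    with wt the weights normalized to sum to one and ybar_w = sum wt_j y_j.
    """
    X, y, w = _check_design(X, y, w)
    wt = w / w.sum()
    ybar = float(wt @ y)
    score = X.T @ (wt * (y - ybar))
    return float(np.max(np.abs(score))) if X.shape[1] else 0.0


def _null_fit(y: np.ndarray, w: np.ndarray, p: int, lam: float, alpha: float) -> LocalFit:
    """Degenerate fallback: intercept-only fit with a pseudo-count shrink.

    Used when all effective outcomes are equal, where the MLE intercept is
    infinite.  The weighted mean is shrunk by a 0.5 pseudo-count relative to
    the total kernel mass, keeping the intercept finite.
    """
    sw = w.sum()
    pbar = (float(w @ y) + 0.5) / (sw + 1.0)
    b0 = float(logit(np.clip(pbar, PROB_CLIP, 1 - PROB_CLIP)))
    beta = np.zeros(p)
    eta = np.full(y.shape, b0)
    wt = w / sw
    obj = float(wt @ (np.logaddexp(0.0, eta) - y * eta))
    return LocalFit(b0, beta, lam, alpha, converged=True, n_iter=0,
                    objective=obj, degenerate=True)


def fit_penalized_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha: float = 1.0,
    *,
    warm_start: LocalFit | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> LocalFit:
    """Fit the weighted elastic-net logistic model at one location.

    Parameters
    ----------
    X, y, w
        Covariates (standardized), binary outcome, nonnegative kernel
        weights for this calibration point (one row of W, possibly with the
        held-out entry removed).
    lam
        Penalty strength on the weight-normalized likelihood scale.
    alpha
        Elastic-net mixing: 1 = lasso, 0 = ridge.
    warm_start
        Previous fit whose coefficients initialize the solver (used along
        descending lambda paths).

    Notes
    -----
    Observations with zero weight are inert; if the weighted outcomes have
    no variation the fit is degenerate and an intercept-only fallback is
    returned with ``degenerate=True`` (callers decide how to treat it).
    Convergence is declared when the largest coefficient change in a full
    IRLS/coordinate-descent cycle falls below ``tol``; non-convergence sets
    ``converged=False`` rather than raising.
    """
    X, y, w = _check_design(X, y, w)
    if not np.isfinite(lam) or lam < 0:
        raise ParameterError(f"lambda must be finite and >= 0, got {lam}")
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    n, p = X.shape
    sw = w.sum()
    wt = w / sw

    eff = y[w > 0]
    if eff.size == 0 or np.all(eff == eff[0]):
        return _null_fit(y, w, p, lam, alpha)

    if warm_start is not None and warm_start.beta.shape == (p,):
        b0 = float(warm_start.intercept)
        beta = warm_start.beta.copy()
    else:
        ybar = float(wt @ y)
        b0 = float(logit(np.clip(ybar, PROB_CLIP, 1 - PROB_CLIP)))
        beta = np.zeros(p)

    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    eta = b0 + X @ beta
    n_sweeps = 0
    converged = False
    # outer IRLS loop; inner cyclic coordinate descent on the quadratic
    for _outer in range(200):
        mu = expit(eta)
        v = np.maximum(mu * (1.0 - mu), VAR_FLOOR)
        u = wt * v                     # working weights
        z = eta + (y - mu) / v         # working response
        r = z - eta                    # working residual
        xu = X * u[:, None]
        denom = np.einsum("jk,jk->k", xu, X) + l2
        su = u.sum()

        max_delta_outer = 0.0
        for _inner in range(1000):
            n_sweeps += 1
            max_delta = 0.0
            # intercept (unpenalized)
            d0 = float(u @ r) / su
            if d0 != 0.0:
                b0 += d0
                r -= d0
                max_delta = abs(d0)
            for k in range(p):
                bk = beta[k]
                rho = float(xu[:, k] @ r) + (denom[k] - l2) * bk
                if l1 > 0.0:
                    bk_new = np.sign(rho) * max(abs(rho) - l1, 0.0) / denom[k]
                else:
                    bk_new = rho / denom[k]
                d = bk_new - bk
                if d != 0.0:
                    beta[k] = bk_new
                    r -= X[:, k] * d
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            max_delta_outer = max(max_delta_outer, max_delta)
            if max_delta < tol or n_sweeps * (p + 1) >= max_iter:
                break
        eta = b0 + X @ beta
        if max_delta_outer < tol:
            converged = True
            break
        if n_sweeps * (p + 1) >= max_iter:
            break

    beta[np.abs(beta) < ZERO_SNAP] = 0.0
    obj = objective_value(X, y, w, b0, beta, lam, alpha)
    return LocalFit(b0, beta, float(lam), float(alpha), converged=converged,
                    n_iter=n_sweeps, objective=obj)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lambdas: np.ndarray,
    alpha: float = 1.0,
    **kwargs,
) -> list[LocalFit]:
    """Fit a descending lambda path with warm starts; one LocalFit per lambda."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or lambdas.size == 0:
        raise ParameterError("lambda path must be a nonempty 1-D sequence")
    if (np.diff(lambdas) > 0).any():
        raise ParameterError("lambda path must be non-increasing")
    fits: list[LocalFit] = []
    prev: LocalFit | None = None
    for lam in lambdas:
        fit = fit_penalized_weighted_logistic(X, y, w, lam, alpha, warm_start=prev, **kwargs)
        fits.append(fit)
        prev = fit if not fit.degenerate else None
    return fits


def predict_probability(fit: LocalFit, x: np.ndarray) -> float | np.ndarray:
    """Inverse-logit prediction mu = logistic(intercept + x . beta).

    Accepts a single p-vector or an (m, p) matrix of covariate rows.
    """
    x = np.asarray(x, dtype=float)
    p = fit.beta.shape[0]
    if x.shape[-1] != p:
        raise InputError(f"expected covariate vector(s) of length {p}, got {x.shape}")
    if not np.isfinite(x).all():
        raise InputError("covariates must be finite")
    eta = fit.intercept + x @ fit.beta
    out = expit(eta)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def kkt_violation(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    fit: LocalFit,
) -> float:
    """Maximum violation of the subgradient optimality conditions.

    Zero (to tolerance) certifies the returned coefficients minimize the
    convex objective; used by the test suite and available for diagnostics.
    """
    X, y, w = _check_design(X, y, w)
    wt = w / w.sum()
    mu = expit(fit.intercept + X @ fit.beta)
    g0 = float(wt @ (mu - y))
    grad = X.T @ (wt * (mu - y)) + fit.lam * (1.0 - fit.alpha) * fit.beta
    l1 = fit.lam * fit.alpha
    viol = abs(g0)
    for k, bk in enumerate(fit.beta):
        if bk != 0.0:
            viol = max(viol, abs(grad[k] + l1 * np.sign(bk)))
        else:
            viol = max(viol, max(abs(grad[k]) - l1, 0.0))
    return viol
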