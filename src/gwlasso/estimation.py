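"""Two-stage estimation of the geographically weighted logistic lasso.

Stage one selects the kernel bandwidth theta and the penalty lambda jointly
by leave-one-out cross-validation: for every candidate theta, each unit i
is held out of its own local fit (the i-th entry is removed from the
kernel weight row W[i, .]), the whole descending lambda path is fitted with
warm starts, and the held-out prediction criterion for unit i is
accumulated per (theta, lambda).  Stage two refits every location with the
full weight rows at the selected pair, producing the N x (p+1) sparse
coefficient field.

The default criterion is the summed held-out binomial deviance
-2 [y log mu + (1-y) log(1-mu)] with clipped probabilities; a
misclassification count is available.  The whole procedure is
deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpatialDataset
from .exceptions import ParameterError
from .kernel import kernel_weights, pairwise_distances
from .solver import PROB_CLIP, LocalFit, fit_path, lambda_max, predict_probability

logger = logging.getLogger(__name__)

CRITERIA = ("deviance", "misclassification")


@dataclass(frozen=True)
class HyperGrid:
    """Candidate bandwidths (ascending) and penalties (descending)."""

    theta_candidates: np.ndarray
    lambda_candidates: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta_candidates, dtype=float)
        lm = np.asarray(self.lambda_candidates, dtype=float)
        if th.ndim != 1 or th.size == 0 or lm.ndim != 1 or lm.size == 0:
            raise ParameterError("theta and lambda candidate lists must be nonempty")
        if not (np.isfinite(th).all() and np.isfinite(lm).all()):
            raise ParameterError("grid candidates must be finite")
        if (th <= 0).any():
            raise ParameterError("theta candidates must be positive")
        if (lm < 0).any():
            raise ParameterError("lambda candidates must be nonnegative")
        if th.size > 1 and not (np.diff(th) > 0).all():
            raise ParameterError("theta candidates must be strictly ascending")
        if lm.size > 1 and not (np.diff(lm) < 0).all():
            raise ParameterError("lambda candidates must be strictly descending")
        object.__setattr__(self, "theta_candidates", th)
        object.__setattr__(self, "lambda_candidates", lm)


@dataclass
class CVGrid:
    """LOO-CV criterion surface over the (theta, lambda) grid."""

    criterion: np.ndarray          # S x T summed held-out criterion
    criterion_name: str
    n_evaluated: np.ndarray        # S x T number of held-out points included
    theta_candidates: np.ndarray
    lambda_candidates: np.ndarray
    n_degenerate: np.ndarray       # S, count of degenerate local fits per theta
    n_path_fits: int = 0           # instrumentation: warm-started path fits run


@dataclass(frozen=True)
class HyperParams:
    """The CV-selected bandwidth/penalty pair and its criterion value."""

    theta_hat: float
    lambda_hat: float
    criterion_value: float


@dataclass
class CoefficientField:
    """Final per-location fits: N x (p+1) matrix, column 0 = intercepts."""

    B: np.ndarray
    theta: float
    lam: float
    alpha: float
    converged: np.ndarray
    degenerate: np.ndarray
    unit_id: np.ndarray | None = None
    covariate_names: list[str] | None = None

    @property
    def intercepts(self) -> np.ndarray:
        return self.B[:, 0]

    @property
    def slopes(self) -> np.ndarray:
        return self.B[:, 1:]

    @property
    def n_selected(self) -> np.ndarray:
        """Number of covariates retained (nonzero slopes) per location."""
        return np.count_nonzero(self.slopes, axis=1)


def _held_out_criterion(y_i: float, mu_i: float, name: str) -> float:
    mu = min(max(mu_i, PROB_CLIP), 1.0 - PROB_CLIP)
    if name == "deviance":
        return -2.0 * (y_i * np.log(mu) + (1.0 - y_i) * np.log(1.0 - mu))
    return float((mu > 0.5) != bool(y_i))


@dataclass
class LOODetails:
    """Per-location diagnostics of one theta row (mainly for auditing)."""

    contributions: np.ndarray      # N x T held-out criterion terms
    mu_held_out: np.ndarray        # N x T held-out predicted probabilities
    fits: list[list[LocalFit]] | None  # per location, per lambda (if kept)


def loo_cv_criterion(
    dataset: SpatialDataset,
    theta: float,
    lambdas: np.ndarray,
    alpha: float = 1.0,
    criterion: str = "deviance",
    D: np.ndarray | None = None,
    keep_fits: bool = False,
    kernel_kwargs: dict | None = None,
):
    """One row of the CV grid: criterion over the lambda path at one theta.

    Returns ``(crit_row, n_eval_row, n_degenerate, details)`` where
    ``crit_row`` has one summed criterion per lambda.  Degenerate local
    fits (no outcome variation under the LOO weights) contribute their
    intercept-only null criterion and are counted, never dropped.
    """
    if criterion not in CRITERIA:
        raise ParameterError(f"criterion must be one of {CRITERIA}")
    n = dataset.n
    if n < 3:
        raise ParameterError("LOO-CV needs N >= 3")
    lambdas = np.asarray(lambdas, dtype=float)
    if D is None:
        D = pairwise_distances(dataset.coords, crs_mode=dataset.crs_mode,
                               metric="haversine" if dataset.crs_mode == "spherical" else "euclidean").D
    W = kernel_weights(D, theta, **(kernel_kwargs or {})).W

    T = lambdas.size
    contrib = np.zeros((n, T))
    mu_out = np.zeros((n, T))
    n_degen = 0
    all_fits: list[list[LocalFit]] | None = [] if keep_fits else None
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        fits = fit_path(dataset.X[keep], dataset.y[keep], W[i, keep], lambdas, alpha)
        if any(f.degenerate for f in fits):
            n_degen += 1
        for t, f in enumerate(fits):
            mu = predict_probability(f, dataset.X[i])
            mu_out[i, t] = mu
            contrib[i, t] = _held_out_criterion(dataset.y[i], mu, criterion)
        if keep_fits:
            all_fits.append(fits)
    crit_row = contrib.sum(axis=0)
    n_eval = np.full(T, n, dtype=int)
    details = LOODetails(contributions=contrib, mu_held_out=mu_out, fits=all_fits)
    return crit_row, n_eval, n_degen, details


def auto_lambda_grid(
    dataset: SpatialDataset,
    theta: float,
    T: int = 10,
    ratio: float = 1e-3,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric lambda path anchored at the most massive-kernel location.

    The anchor is the local lambda_max at the location whose kernel row has
    the largest total mass under ``theta``; the path descends geometrically
    to ``ratio`` times the anchor over ``T`` points.
    """
    if T < 1:
        raise ParameterError("T must be >= 1")
    if D is None:
        D = pairwise_distances(dataset.coords).D
    W = kernel_weights(D, theta).W
    i_star = int(np.argmax(W.sum(axis=1)))
    anchor = lambda_max(dataset.X, dataset.y, W[i_star])
    if anchor <= 0:
        anchor = 1.0
    if T == 1:
        return np.array([anchor])
    return anchor * np.geomspace(1.0, ratio, T)


def select_hyperparameters(
    dataset: SpatialDataset,
    grid: HyperGrid,
    alpha: float = 1.0,
    search_mode: str = "grid",
    criterion: str = "deviance",
    D: np.ndarray | None = None,
):
    """Stage one: joint LOO-CV selection of (theta, lambda).

    ``search_mode='grid'`` evaluates the full S x T surface (the
    reproducible default); ``'golden'`` runs a golden-section search over
    theta on a unimodality assumption, fitting the full lambda path at each
    probed bandwidth.  Ties break to the smallest theta, then the largest
    lambda (the simpler, sparser model).

    Returns ``(HyperParams, CVGrid)``.
    """
    if search_mode not in ("grid", "golden"):
        raise ParameterError("search_mode must be 'grid' or 'golden'")
    if D is None:
        D = pairwise_distances(dataset.coords, crs_mode=dataset.crs_mode,
                               metric="haversine" if dataset.crs_mode == "spherical" else "euclidean").D
    thetas = grid.theta_candidates
    lambdas = grid.lambda_candidates

    if search_mode == "golden":
        thetas = _golden_section_thetas(dataset, grid, alpha, criterion, D)

    S, T = thetas.size, lambdas.size
    crit = np.zeros((S, T))
    n_eval = np.zeros((S, T), dtype=int)
    n_degen = np.zeros(S, dtype=int)
    for s, th in enumerate(thetas):
        crit[s], n_eval[s], n_degen[s], _ = loo_cv_criterion(
            dataset, th, lambdas, alpha, criterion, D=D)
        logger.info("CV theta=%g: best %s %.6g", th, criterion, crit[s].min())
    cv = CVGrid(criterion=crit, criterion_name=criterion, n_evaluated=n_eval,
                theta_candidates=thetas, lambda_candidates=lambdas,
                n_degenerate=n_degen, n_path_fits=S * dataset.n)
    # row-major argmin over (ascending theta, descending lambda) realizes the
    # tie-break: smallest theta first, then largest lambda
    s_best, t_best = np.unravel_index(int(np.argmin(crit)), crit.shape)
    params = HyperParams(theta_hat=float(thetas[s_best]),
                         lambda_hat=float(lambdas[t_best]),
                         criterion_value=float(crit[s_best, t_best]))
    return params, cv


def _golden_section_thetas(dataset, grid, alpha, criterion, D, n_probes: int = 8):
    """Probe bandwidths by golden-section refinement of min-over-lambda CV."""
    lo, hi = float(grid.theta_candidates[0]), float(grid.theta_candidates[-1])
    if lo == hi:
        return np.array([lo])
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    cache: dict[float, float] = {}

    def f(th: float) -> float:
        if th not in cache:
            row, *_ = loo_cv_criterion(dataset, th, grid.lambda_candidates,
                                       alpha, criterion, D=D)
            cache[th] = float(row.min())
        return cache[th]

    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    f(a), f(b)
    for _ in range(n_probes):
        if f(c) < f(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return np.array(sorted(cache))


def fit_gwl(
    dataset: SpatialDataset,
    params: HyperParams | tuple[float, float],
    alpha: float = 1.0,
    D: np.ndarray | None = None,
    kernel_kwargs: dict | None = None,
) -> CoefficientField:
    """Stage two: final per-location fits with full kernel weight rows.

    Every location is fitted at the selected (theta, lambda) with no LOO
    exclusion; the result is the N x (p+1) sparse coefficient field.
    """
    if isinstance(params, HyperParams):
        theta, lam = params.theta_hat, params.lambda_hat
    else:
        theta, lam = params
    if D is None:
        D = pairwise_distances(dataset.coords, crs_mode=dataset.crs_mode,
                               metric="haversine" if dataset.crs_mode == "spherical" else "euclidean").D
    W = kernel_weights(D, theta, **(kernel_kwargs or {})).W
    n, p = dataset.n, dataset.p
    B = np.zeros((n, p + 1))
    converged = np.zeros(n, dtype=bool)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        fit = fit_path(dataset.X, dataset.y, W[i], np.array([lam]), alpha)[0]
        B[i, 0] = fit.intercept
        B[i, 1:] = fit.beta
        converged[i] = fit.converged
        degenerate[i] = fit.degenerate
        if fit.degenerate:
            logger.warning("degenerate local fit at unit %s", dataset.unit_id[i])
    return CoefficientField(B=B, theta=float(theta), lam=float(lam), alpha=float(alpha),
                            converged=converged, degenerate=degenerate,
                            unit_id=dataset.unit_id,
                            covariate_names=list(dataset.covariate_names))
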