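"""Preprocessing and the area-based health coverage index.

The index follows Gordon's logistic-regression construction: each unit's
score is a weighted sum of the covariates its local model retained, with
the estimated odds ratios exp(beta) as weights,

    raw_i = sum_{m : beta_im != 0} exp(beta_im) * x_im ,

optionally min-max normalized to [0, 1] (the default), clipped at zero, and
finally rescaled by an adjustment constant k chosen so the
household-weighted average of the index equals a known population rate
(e.g. the national screening rate):

    k = target_average * sum_i h_i / sum_i h_i * raw~_i ,   ind_i = k * raw~_i .

Also provided: median binarization of continuous rates into the modelling
outcome, covariate standardization, and Spearman rank-correlation
validation of the index against external series (with an exact permutation
p-value at very small N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from .dataset import SpatialDataset
from .exceptions import InputError, NumericalError, ParameterError

EXACT_PERM_MAX_N = 9


def binarize_by_median(rates: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binarize a continuous rate at its sample median (strictly above -> 1).

    Ties at the threshold map to 0, so the number of ones never exceeds
    floor(N/2) under the median rule.  ``threshold`` overrides the median.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or rates.size < 2:
        raise InputError("rates must be a 1-D vector with N >= 2")
    if not np.isfinite(rates).all():
        raise InputError("rates must be finite")
    if np.ptp(rates) == 0 and threshold is None:
        raise InputError("all rates identical: no variation to binarize")
    thr = float(np.median(rates)) if threshold is None else float(threshold)
    return (rates > thr).astype(float)


def standardize(X_raw: np.ndarray, names: list[str] | None = None):
    """Column z-scores with sample (n-1) standard deviation.

    Returns ``(X, mean, sd)``; the mean/sd allow exact round-tripping.
    Raises on constant columns, naming the offending covariate.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2:
        raise InputError("X_raw must be 2-D")
    if not np.isfinite(X_raw).all():
        raise InputError("covariates must be finite")
    mean = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        labels = [names[k] if names else f"column {k}" for k in zero]
        raise InputError(f"constant covariate(s) cannot be standardized: {labels}")
    return (X_raw - mean) / sd, mean, sd


def unstandardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(X, dtype=float) * sd + mean


@dataclass
class IndexResult:
    """Per-unit coverage index with its calibration constant."""

    ind: np.ndarray
    raw: np.ndarray
    k: float
    target_average: float
    normalization: str


def compute_index(
    B: np.ndarray,
    dataset: SpatialDataset,
    target_average: float,
    normalization: str = "minmax",
) -> IndexResult:
    """Build the coverage index from a coefficient field and calibrate k.

    Parameters
    ----------
    B
        N x (p+1) coefficient matrix, column 0 the intercepts; only
        covariates with exactly nonzero slopes contribute (covariates the
        lasso dropped contribute 0, not exp(0) * x).
    dataset
        Supplies the standardized covariates and, when present, household
        counts; without households all units weigh equally (logged upstream).
    target_average
        Known population average the household-weighted index mean is
        calibrated to (e.g. 0.1018 for a 10.18% screening rate).
    normalization
        ``minmax`` (default) rescales raw scores to [0, 1] before
        calibration; ``none`` uses the raw scores, clipping negatives to 0.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape != (dataset.n, dataset.p + 1):
        raise InputError(f"B must be (N, p+1) = ({dataset.n}, {dataset.p + 1}), got {B.shape}")
    if not np.isfinite(target_average) or target_average <= 0:
        raise ParameterError(f"target_average must be positive, got {target_average}")
    if normalization not in ("none", "minmax"):
        raise ParameterError(f"normalization must be 'none' or 'minmax', got {normalization!r}")

    slopes = B[:, 1:]
    contrib = np.where(slopes != 0.0, np.exp(slopes) * dataset.X, 0.0)
    raw = contrib.sum(axis=1)

    if normalization == "minmax":
        span = raw.max() - raw.min()
        if span == 0:
            scaled = np.zeros_like(raw)
        else:
            scaled = (raw - raw.min()) / span
    else:
        scaled = raw.copy()
    scaled = np.clip(scaled, 0.0, None)

    h = dataset.households if dataset.households is not None else np.ones(dataset.n)
    denom = float(h @ scaled)
    if denom == 0:
        raise NumericalError("all index scores are zero; cannot calibrate k")
    k = target_average * float(h.sum()) / denom
    return IndexResult(ind=k * scaled, raw=raw, k=k,
                       target_average=float(target_average), normalization=normalization)


def _spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def spearman_validate(ind: np.ndarray, external: np.ndarray):
    """Spearman rank correlation of the index with an external series.

    Ties get average ranks.  The two-sided p-value uses the t
    approximation, except for N <= 9 where the exact permutation
    distribution (all N! orderings) is enumerated.

    Returns ``(rho, p_value)``.
    """
    a = np.asarray(ind, dtype=float)
    b = np.asarray(external, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired 1-D vectors required")
    n = a.size
    if n < 4:
        raise InputError("need N >= 4 for a correlation test")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("zero variance in one of the vectors: correlation undefined")

    rho = _spearman_rho(a, b)
    if n <= EXACT_PERM_MAX_N:
        hits = 0
        total = 0
        obs = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            total += 1
            if abs(_spearman_rho(a, b[list(perm)])) >= obs:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
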