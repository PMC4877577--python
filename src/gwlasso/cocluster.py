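"""Latent block model co-clustering of the coefficient field.

The N x (p+1) sparse coefficient matrix is summarized by simultaneously
clustering its rows (areal units) and columns (intercept + covariates)
into G_rows x G_cols homogeneous blocks: a mixture model in which cell
(i, j) is drawn from a distribution indexed only by the block
(row-cluster of i, column-cluster of j).  Blocks with large means flag
groups of areas sharing a characteristic set of predictors.

Estimation uses classification EM (hard assignments), which monotonically
increases the complete-data log-likelihood, initialized by separate
k-means runs on rows and columns, with restarts.  Emissions are Gaussian
per block by default; a Bernoulli option models the binary nonzero
pattern instead of the coefficient values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import InputError, NumericalError, ParameterError

VAR_FLOOR = 1e-6
BERN_CLIP = 1e-6


@dataclass
class CoClusterResult:
    """Row/column partition with per-block parameters and the EM trace."""

    row_labels: np.ndarray
    col_labels: np.ndarray
    block_means: np.ndarray
    block_variances: np.ndarray
    log_likelihood: float
    ll_trace: np.ndarray
    n_restarts_used: int
    seed: int
    emissions: str = "gaussian"


def _block_stats(M, r, c, G, H):
    """Per-block counts, means and (floored) variances from hard labels."""
    R = np.eye(G)[r]                   # N x G indicator
    C = np.eye(H)[c]                   # Q x H indicator
    n_blk = np.outer(np.bincount(r, minlength=G), np.bincount(c, minlength=H)).astype(float)
    s1 = R.T @ M @ C
    s2 = R.T @ (M * M) @ C
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_blk > 0, s1 / np.maximum(n_blk, 1), 0.0)
        var = np.where(n_blk > 0, s2 / np.maximum(n_blk, 1) - mean**2, 1.0)
    var = np.maximum(var, VAR_FLOOR)
    return n_blk, mean, var


def _complete_ll(M, r, c, mean, var, pi, rho, emissions):
    N, Q = M.shape
    ll = float(np.log(pi[r]).sum() + np.log(rho[c]).sum())
    blk_r = mean[r]          # N x H expanded by row labels
    mu = blk_r[np.arange(N)[:, None], c[None, :]]
    if emissions == "gaussian":
        v = var[r][np.arange(N)[:, None], c[None, :]]
        ll += float(np.sum(-0.5 * (np.log(2 * np.pi * v) + (M - mu) ** 2 / v)))
    else:
        p = np.clip(mu, BERN_CLIP, 1 - BERN_CLIP)
        ll += float(np.sum(M * np.log(p) + (1 - M) * np.log(1 - p)))
    return ll


def _row_scores(M, c, mean, var, pi, H, emissions):
    """N x G matrix of classification log-likelihood scores for row moves."""
    C = np.eye(H)[c]                    # Q x H
    S1 = M @ C                          # N x H sums per column-cluster
    S2 = (M * M) @ C
    nh = np.bincount(c, minlength=H).astype(float)
    if emissions == "gaussian":
        # sum over h of: -n_h/2 log(2 pi v_gh) - (S2 - 2 mu S1 + n_h mu^2)/(2 v_gh)
        logv = np.log(2 * np.pi * var)             # G x H
        quad = (S2[:, None, :] - 2 * mean[None] * S1[:, None, :]
                + nh[None, None, :] * mean[None] ** 2) / var[None]
        scores = -0.5 * (nh[None, None, :] * logv[None] + quad).sum(axis=2)
    else:
        p = np.clip(mean, BERN_CLIP, 1 - BERN_CLIP)
        scores = (S1[:, None, :] * np.log(p)[None]
                  + (nh[None, None, :] - S1[:, None, :]) * np.log(1 - p)[None]).sum(axis=2)
    return scores + np.log(pi)[None, :]


def fit_latent_block_model(
    M: np.ndarray,
    G_rows: int,
    G_cols: int,
    seed: int = 0,
    n_restarts: int = 20,
    emissions: str = "gaussian",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CoClusterResult:
    """Fit a G_rows x G_cols latent block model by classification EM.

    The best of ``n_restarts`` differently-initialized runs (by final
    complete-data log-likelihood) is returned; results are deterministic
    given ``seed``.  Restarts whose partitions collapse (an empty row or
    column cluster) are discarded; an error is raised only if every
    restart collapses.

    ``emissions='bernoulli'`` expects a 0/1 matrix (e.g. the nonzero
    pattern of a coefficient field).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise InputError("M must be a 2-D matrix")
    if not np.isfinite(M).all():
        raise InputError("M must be finite")
    N, Q = M.shape
    if not (1 <= G_rows <= N and 1 <= G_cols <= Q):
        raise ParameterError(f"cluster counts must satisfy 1 <= G_rows <= {N}, 1 <= G_cols <= {Q}")
    if emissions not in ("gaussian", "bernoulli"):
        raise ParameterError("emissions must be 'gaussian' or 'bernoulli'")
    if emissions == "bernoulli" and not np.isin(M, (0.0, 1.0)).all():
        raise InputError("bernoulli emissions require a binary matrix")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")

    best: CoClusterResult | None = None
    for restart in range(n_restarts):
        rs = (int(seed) + 1009 * restart) % (2**31 - 1)
        r, c = _init_labels(M, G_rows, G_cols, rs, jitter=restart > 0)
        out = _cem_run(M, r, c, G_rows, G_cols, emissions, max_iter, tol)
        if out is None:
            continue
        r, c, mean, var, trace = out
        if best is None or trace[-1] > best.log_likelihood:
            best = CoClusterResult(row_labels=r, col_labels=c, block_means=mean,
                                   block_variances=var, log_likelihood=float(trace[-1]),
                                   ll_trace=np.asarray(trace), n_restarts_used=restart + 1,
                                   seed=int(seed), emissions=emissions)
    if best is None:
        raise NumericalError("all co-clustering restarts collapsed to empty clusters")
    return best


def _init_labels(M, G, H, rs, jitter):
    km_r = KMeans(n_clusters=G, n_init=2, random_state=rs).fit(M)
    km_c = KMeans(n_clusters=H, n_init=2, random_state=rs + 1).fit(M.T)
    r = km_r.labels_.copy()
    c = km_c.labels_.copy()
    if jitter:
        rng = np.random.default_rng(rs)
        # perturb a small fraction of labels so restarts explore distinct basins
        for labels, k in ((r, G), (c, H)):
            m = max(1, labels.size // 10)
            pos = rng.choice(labels.size, size=m, replace=False)
            labels[pos] = rng.integers(0, k, size=m)
    return r, c


def _cem_run(M, r, c, G, H, emissions, max_iter, tol):
    N, Q = M.shape
    trace: list[float] = []
    for _it in range(max_iter):
        if np.unique(r).size < G or np.unique(c).size < H:
            return None
        _, mean, var = _block_stats(M, r, c, G, H)
        pi = np.bincount(r, minlength=G) / N
        rho = np.bincount(c, minlength=H) / Q
        # row reassignment
        r = np.argmax(_row_scores(M, c, mean, var, pi, H, emissions), axis=1)
        if np.unique(r).size < G:
            return None
        _, mean, var = _block_stats(M, r, c, G, H)
        pi = np.bincount(r, minlength=G) / N
        # column reassignment (transpose symmetry)
        c = np.argmax(_row_scores(M.T, r, mean.T, var.T, rho, G, emissions), axis=1)
        if np.unique(c).size < H:
            return None
        _, mean, var = _block_stats(M, r, c, G, H)
        pi = np.bincount(r, minlength=G) / N
        rho = np.bincount(c, minlength=H) / Q
        ll = _complete_ll(M, r, c, mean, var, pi, rho, emissions)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            break
    return r, c, mean, var, trace


def block_summary(result: CoClusterResult, covariate_names, unit_ids, top: int = 3):
    """Tabular report of the co-clustering.

    Returns ``(blocks, row_clusters)``: ``blocks`` lists every (row-cluster,
    column-cluster) pair with its mean, variance and occupancy;
    ``row_clusters`` lists each row cluster's member units and the
    covariates of its ``top`` largest-|mean| column clusters.
    """
    import pandas as pd

    names = list(covariate_names)
    units = list(unit_ids)
    if len(units) != result.row_labels.size or len(names) != result.col_labels.size:
        raise InputError("unit_ids / covariate_names lengths must match the clustered matrix")
    G, H = result.block_means.shape
    occ = np.outer(np.bincount(result.row_labels, minlength=G),
                   np.bincount(result.col_labels, minlength=H))
    blocks = pd.DataFrame(
        [(g, h, result.block_means[g, h], result.block_variances[g, h], int(occ[g, h]))
         for g in range(G) for h in range(H)],
        columns=["row_cluster", "col_cluster", "mean", "variance", "n_cells"],
    )
    rows = []
    col_members = {h: [names[j] for j in np.flatnonzero(result.col_labels == h)]
                   for h in range(H)}
    for g in range(G):
        members = [units[i] for i in np.flatnonzero(result.row_labels == g)]
        order = np.argsort(-np.abs(result.block_means[g]))[:top]
        top_desc = "; ".join(
            f"col_cluster {h} (mean {result.block_means[g, h]:.6g}): "
            + ", ".join(map(str, col_members[h]))
            for h in order)
        rows.append((g, len(members), ", ".join(map(str, members)), top_desc))
    row_clusters = pd.DataFrame(rows, columns=["row_cluster", "n_units", "units",
                                               "top_column_clusters"])
    return blocks, row_clusters
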