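"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately written from scratch (plain Newton/IRLS,
proximal subgradient descent, exhaustive permutation enumeration) and
shares no code with the package, so agreement between the two routes is
meaningful.
"""

from itertools import permutations

import numpy as np


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def newton_weighted_logistic(X, y, w, max_iter=200, tol=1e-12):
    """Unpenalized weighted logistic MLE by damped Newton iterations.

    Returns the length p+1 vector (intercept first).  Weights are
    normalized to sum to one, matching the package's loss convention
    (which does not change the unpenalized optimum).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    wt = np.asarray(w, float) / np.sum(w)
    Z = np.column_stack([np.ones(len(y)), X])
    b = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        mu = _sigmoid(Z @ b)
        grad = Z.T @ (wt * (mu - y))
        H = (Z * (wt * mu * (1 - mu))[:, None]).T @ Z
        step = np.linalg.solve(H + 1e-12 * np.eye(len(b)), grad)
        b_new = b - step
        if np.max(np.abs(b_new - b)) < tol:
            return b_new
        b = b_new
    return b


def penalized_objective(X, y, w, intercept, beta, lam, alpha):
    """Weight-normalized elastic-net logistic objective, written independently."""
    wt = np.asarray(w, float) / np.sum(w)
    eta = intercept + np.asarray(X, float) @ beta
    nll = float(wt @ (np.logaddexp(0.0, eta) - np.asarray(y, float) * eta))
    pen = lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * float(beta @ beta))
    return nll + pen


def proximal_gradient_lasso(X, y, w, lam, alpha=1.0, n_iter=30000):
    """Brute-force minimizer: proximal (sub)gradient descent with a fixed
    step chosen from the Lipschitz constant of the smooth part."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    wt = np.asarray(w, float) / np.sum(w)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    # smooth part: normalized nll + ridge term; Lipschitz bound 1/4 |Zw^T Z|_2
    L = 0.25 * np.linalg.norm((Z * wt[:, None]).T @ Z, 2) + lam * (1 - alpha)
    step = 1.0 / L
    b0, beta = 0.0, np.zeros(p)
    thr = step * lam * alpha
    for _ in range(n_iter):
        mu = _sigmoid(b0 + X @ beta)
        g = Z.T @ (wt * (mu - y))
        b0 -= step * g[0]
        beta = beta - step * (g[1:] + lam * (1 - alpha) * beta)
        beta = np.sign(beta) * np.maximum(np.abs(beta) - thr, 0.0)
    return b0, beta


def _average_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(a, b):
    ra = _average_ranks(a) - (len(a) + 1) / 2.0
    rb = _average_ranks(b) - (len(b) + 1) / 2.0
    return float(ra @ rb / np.sqrt((ra @ ra) * (rb @ rb)))


def spearman_exact_p(a, b):
    """Two-sided p-value by exhaustive enumeration of all N! orderings."""
    b = np.asarray(b, float)
    obs = abs(spearman_rho(a, b)) - 1e-12
    hits = total = 0
    for perm in permutations(range(len(b))):
        total += 1
        if abs(spearman_rho(a, b[list(perm)])) >= obs:
            hits += 1
    return hits / total
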