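"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — O(p^3) exhaustive scans and direct
likelihood maximization — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def naive_single_linkage_heights(d: np.ndarray) -> np.ndarray:
    """Single-linkage merge heights by exhaustive pair scan per step."""
    p = d.shape[0]
    clusters = [frozenset([i]) for i in range(p)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return np.asarray(heights)


def prim_mst_weights(d: np.ndarray) -> np.ndarray:
    """Edge weights of the minimum spanning tree (Prim's algorithm)."""
    p = d.shape[0]
    in_tree = np.zeros(p, dtype=bool)
    in_tree[0] = True
    best = d[0].copy()
    weights = []
    for _ in range(p - 1):
        best[in_tree] = np.inf
        j = int(np.argmin(best))
        weights.append(best[j])
        in_tree[j] = True
        best = np.minimum(best, d[j])
    return np.asarray(weights)


def threshold_components(d: np.ndarray, h: float) -> np.ndarray:
    """Flat clusters as connected components of the graph {d_ij <= h}.

    Independent route to the single-linkage cut: genes share a flat cluster
    iff they are connected by a path of edges no longer than ``h``.
    """
    p = d.shape[0]
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if d[i, j] <= h:
                parent[find(i)] = find(j)
    return np.asarray([find(i) for i in range(p)])


def maximize_logistic_loglik(X: np.ndarray, y: np.ndarray):
    """Direct maximization of the Bernoulli log-likelihood (BFGS).

    Returns ``(beta, loglik)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)

    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(b):
        return X.T @ (expit(X @ b) - y)

    res = minimize(
        nll,
        np.zeros(X.shape[1]),
        jac=grad,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 1000},
    )
    return res.x, -res.fun
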