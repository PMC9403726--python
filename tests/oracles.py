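"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by the most transparent method
available (exhaustive enumeration, Floyd-Warshall, explicit normal
equations) so the implementation under test is checked against code that
shares none of its structure.
"""

import itertools

import numpy as np
from scipy import stats


def floyd_warshall(w):
    """All-pairs shortest paths with lengths 1/weight, by triple loop."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency(w):
    """Mean inverse shortest-path length over ordered pairs (brute force)."""
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def strengths(w):
    return np.array([sum(w[i, j] for j in range(w.shape[0])) for i in range(w.shape[0])])


def threshold_sort_and_cut(w, target):
    """Keep the k strongest edges by explicit sorting (independent route)."""
    n = w.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
    k = int(np.floor(target * n * (n - 1) / 2 + 0.5))
    if len(pairs) <= k:
        return w.copy()
    pairs.sort(key=lambda p: (-w[p[0], p[1]], p))
    out = np.zeros_like(w)
    for i, j in pairs[:k]:
        out[i, j] = out[j, i] = w[i, j]
    return out


def exhaustive_core_periphery(w, quality_fn):
    """Global optimum of the partition quality by enumerating all labelings."""
    n = w.shape[0]
    best_q, best = -np.inf, None
    for bits in itertools.product([False, True], repeat=n):
        is_core = np.array(bits)
        q = quality_fn(w, is_core)
        if q > best_q:
            best_q, best = q, is_core
    return best, best_q


def connected_components_bfs(pairs):
    """Components of an edge list by breadth-first search over adjacency."""
    adj = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen, comps = set(), []
    for start in sorted(adj):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def ols_t(x_cols, y):
    """Scalar OLS t for the second column via explicit normal equations."""
    X = np.column_stack(x_cols)
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[1], beta[1] / np.sqrt(cov[1, 1])


def partial_spearman_normal_equations(x, y, covs):
    """Rank everything, then solve the small normal equations explicitly."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack([np.ones(len(x))] + [stats.rankdata(c) for c in covs])
    bx = np.linalg.solve(Z.T @ Z, Z.T @ rx)
    by = np.linalg.solve(Z.T @ Z, Z.T @ ry)
    ex, ey = rx - Z @ bx, ry - Z @ by
    return (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values evaluated from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return adj
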