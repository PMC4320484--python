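"""Independent from-scratch oracles used to cross-check the implementation.

Each function here re-derives a quantity from first principles (explicit
rank sums, normal equations, NIPALS iterations, naive agglomeration) and is
deliberately kept independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def kruskal_h_oracle(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction, from explicit rank sums."""
    flat = np.concatenate(groups)
    n = len(flat)
    ranks = stats.rankdata(flat)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def anova_f_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p from explicit sums of squares."""
    flat = np.concatenate(groups)
    grand = flat.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(flat) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return f, float(stats.f.sf(f, df1, df2))


def tukey_p_oracle(groups: list[np.ndarray]) -> np.ndarray:
    """Pairwise Tukey-Kramer p-values via the studentized range distribution."""
    k = len(groups)
    n_g = np.array([len(g) for g in groups])
    df2 = int(n_g.sum()) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df2
    means = np.array([g.mean() for g in groups])
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / n_g[i] + 1.0 / n_g[j]))
            q = abs(means[i] - means[j]) / se
            p[i, j] = p[j, i] = float(stats.studentized_range.sf(q, k, df2))
    return p


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def granger_f_oracle(x: np.ndarray, y: np.ndarray, lag: int = 1) -> tuple[float, float]:
    """Nested-model F for lag-l causality via explicit normal equations."""
    T = len(y)
    target = y[lag:]
    ones = np.ones(T - lag)
    ylags = np.column_stack([y[lag - k - 1 : T - k - 1] for k in range(lag)])
    xlags = np.column_stack([x[lag - k - 1 : T - k - 1] for k in range(lag)])
    restricted = np.column_stack([ones, ylags])
    unrestricted = np.column_stack([ones, ylags, xlags])

    def rss(design):
        beta = np.linalg.solve(design.T @ design, design.T @ target)
        resid = target - design @ beta
        return float(resid @ resid)

    rss0, rss1 = rss(restricted), rss(unrestricted)
    df1 = lag
    df2 = T - lag - (1 + 2 * lag)
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    return f, float(stats.f.sf(f, df1, df2))


def nipals_pls2_oracle(X: np.ndarray, Y: np.ndarray, ncomp: int, tol: float = 1e-10):
    """Classical NIPALS PLS2 (regression-mode deflation), no sparsity.

    Returns (scores, x_weights) with each weight vector's largest-|entry|
    made positive, matching a deterministic sign convention.
    """
    Xh = X.copy().astype(float)
    Yh = Y.copy().astype(float)
    n, p = X.shape
    scores = np.zeros((n, ncomp))
    weights = np.zeros((p, ncomp))
    for h in range(ncomp):
        u = Yh[:, int(np.argmax(Yh.var(axis=0)))]
        for _ in range(10000):
            w = Xh.T @ u
            w /= np.linalg.norm(w)
            t = Xh @ w
            q = Yh.T @ t / (t @ t)
            u_new = Yh @ q / (q @ q)
            if np.linalg.norm(u_new - u) < tol * max(np.linalg.norm(u), 1e-30):
                u = u_new
                break
            u = u_new
        w = Xh.T @ u
        w /= np.linalg.norm(w)
        t = Xh @ w
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t = -w, -t
        pvec = Xh.T @ t / (t @ t)
        qvec = Yh.T @ t / (t @ t)
        Xh = Xh - np.outer(t, pvec)
        Yh = Yh - np.outer(t, qvec)
        scores[:, h] = t
        weights[:, h] = w
    return scores, weights


def complete_linkage_oracle(points: np.ndarray):
    """Naive agglomerative complete-linkage: list of (merged set, height)."""
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }

    def cluster_dist(a: frozenset, b: frozenset) -> float:
        return max(dist[(min(i, j), max(i, j))] for i in a for j in b)

    merges = []
    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                d = cluster_dist(clusters[ai], clusters[bi])
                if best is None or d < best[0]:
                    best = (d, ai, bi)
        d, ai, bi = best
        merged = clusters[ai] | clusters[bi]
        merges.append((set(merged), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)] + [merged]
    return merges
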