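"""Independent brute-force oracles used to validate the implementations.

Each function here is written as plainly as possible (nested loops,
no shared code with the package) so it can serve as an independent
reference for the optimized/library-backed code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def sw_score_bruteforce(query, subject, matrix, gap_open, gap_extend):
    """Full affine-gap Smith-Waterman DP; gap of length L costs
    gap_open + gap_extend * L (BLAST convention)."""
    n, m = len(query), len(subject)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    e = [[neg] * (m + 1) for _ in range(n + 1)]
    f = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - gap_open - gap_extend, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open - gap_extend, f[i - 1][j] - gap_extend)
            diag = h[i - 1][j - 1] + matrix[query[i - 1], subject[j - 1]]
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def bh_stepup(pvalues):
    """Manual Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(prev, p[idx] * m / rank_from_top)
        adjusted[idx] = value
        prev = value
    return adjusted


def mcl_iterate(adjacency, inflation, self_loop=1.0, tol=1e-6, max_iter=100):
    """Plain-loop MCL matrix iteration returning the final matrix."""
    n = len(adjacency)
    m = [[float(adjacency[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        m[i][i] += self_loop
    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s
        return mat
    m = normalize(m)
    for _ in range(max_iter):
        exp = [
            [sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
            for i in range(n)
        ]
        inf = normalize([[exp[i][j] ** inflation for j in range(n)] for i in range(n)])
        delta = max(
            abs(inf[i][j] - m[i][j]) for i in range(n) for j in range(n)
        )
        m = inf
        if delta < tol:
            break
    return m


def mcl_clusters_from_matrix(matrix, labels):
    """Cluster extraction from a converged MCL matrix (strongest attractor,
    merged via union-find) — mirrors the documented interpretation."""
    n = len(labels)
    assign = [max(range(n), key=lambda i: matrix[i][j]) for j in range(n)]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for j in range(n):
        ri, rj = find(assign[j]), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for j in range(n):
        groups.setdefault(find(j), set()).add(labels[j])
    return sorted(groups.values(), key=lambda s: sorted(map(str, s)))


def entanglement_bruteforce(t1, t2):
    """Exhaustive search over all child-order flip configurations of both
    trees; returns the minimal normalized mean rank displacement."""

    def orders(tree):
        internals = [n for n in tree.traverse() if not n.is_tip()]
        result = set()
        for flips in itertools.product([False, True], repeat=len(internals)):
            flipset = {id(n) for n, fl in zip(internals, flips) if fl}
            seq = []

            def walk(node):
                if node.is_tip():
                    seq.append(node.name)
                    return
                kids = list(node.children)
                if id(node) in flipset:
                    kids = kids[::-1]
                for k in kids:
                    walk(k)

            walk(tree)
            result.add(tuple(seq))
        return result

    leaves = sorted(t.name for t in t1.tips())
    n = len(leaves)
    norm = n / 2 if n % 2 == 0 else (n * n - 1) / (2 * n)
    best = None
    for o1 in orders(t1):
        r1 = {name: i for i, name in enumerate(o1)}
        for o2 in orders(t2):
            disp = sum(abs(r1[name] - i) for i, name in enumerate(o2)) / n
            if best is None or disp < best:
                best = disp
    return best / norm


def average_linkage_trace(rows):
    """Naive O(n^3) average-linkage agglomeration on Euclidean distances.

    Returns the merge trace as a list of (cluster_a, cluster_b, height)
    with clusters given as frozensets of row indices.
    """
    points = [np.asarray(r, dtype=float) for r in rows]
    clusters = {i: frozenset([i]) for i in range(len(points))}
    trace = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dists = [
                float(np.linalg.norm(points[i] - points[j]))
                for i in clusters[a]
                for j in clusters[b]
            ]
            d = sum(dists) / len(dists)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        trace.append((clusters[a], clusters[b], d))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return trace


def median_of_ratios(matrix):
    """Textbook median-of-ratios factors for a genes x samples array."""
    mat = np.asarray(matrix, dtype=float)
    keep = (mat > 0).all(axis=1)
    ref = np.exp(np.log(mat[keep]).mean(axis=1))
    factors = []
    for j in range(mat.shape[1]):
        ratios = mat[keep, j] / ref
        factors.append(float(np.median(ratios)))
    return factors


def welch_formula(a, b):
    """Welch's t statistic and two-sided p from the textbook formulas."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def anova_ss_balanced(values, factor_a, factor_b):
    """Classical sums of squares for a balanced two-factor layout."""
    import pandas as pd

    df = pd.DataFrame({"y": values, "a": factor_a, "b": factor_b})
    grand = df["y"].mean()
    n = len(df)
    levels_a = df["a"].unique()
    levels_b = df["b"].unique()
    n_a = {a: (df["a"] == a).sum() for a in levels_a}
    n_b = {b: (df["b"] == b).sum() for b in levels_b}
    ss_a = sum(n_a[a] * (df.loc[df["a"] == a, "y"].mean() - grand) ** 2 for a in levels_a)
    ss_b = sum(n_b[b] * (df.loc[df["b"] == b, "y"].mean() - grand) ** 2 for b in levels_b)
    ss_cells = 0.0
    ss_err = 0.0
    for a in levels_a:
        for b in levels_b:
            cell = df.loc[(df["a"] == a) & (df["b"] == b), "y"]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    return {"a": float(ss_a), "b": float(ss_b), "a:b": float(ss_ab), "error": float(ss_err)}
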