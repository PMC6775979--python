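"""Independent brute-force oracles used to validate the fast implementations.

Every function here is deliberately written in the most literal way
possible (explicit enumeration, grid search, per-branch classification)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def unifrac_brute(tree, counts_a, counts_b, otu_ids, weighted=False,
                  normalized=True):
    """Per-branch classification UniFrac for a single sample pair."""
    col = {o: j for j, o in enumerate(otu_ids)}
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    ra, rb = a / a.sum(), b / b.sum()
    num = den = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.edge.length is None:
            continue
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        idx = [col[t] for t in tips if t in col]
        ln = node.edge.length
        if weighted:
            pa = ra[idx].sum() if idx else 0.0
            pb = rb[idx].sum() if idx else 0.0
            num += ln * abs(pa - pb)
            den += ln * (pa + pb)
        else:
            in_a = any(a[i] > 0 for i in idx)
            in_b = any(b[i] > 0 for i in idx)
            if in_a != in_b:
                num += ln
            if in_a or in_b:
                den += ln
    if weighted and not normalized:
        return num
    return num / den if den > 0 else 0.0


def ward_merge_brute(points):
    """Ward merge sequence by recomputing the ESS increase of every merge."""
    points = np.asarray(points, dtype=float)
    clusters = {i: [i] for i in range(len(points))}
    next_id = len(points)
    merges = []

    def ess(members):
        sub = points[members]
        return ((sub - sub.mean(axis=0)) ** 2).sum()

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            delta = ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
            if best is None or delta < best[0] - 1e-12:
                best = (delta, i, j)
        _, i, j = best
        merges.append((i, j))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


def procrustes_grid(X, Y, refine=6):
    """min ||Xc - c*Yc R(theta)||^2 over rotation angle and scale (2-D only)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def m2(theta, c, reflect):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        if reflect:
            R = R @ np.diag([1.0, -1.0])
        return ((Xc - c * Yc @ R) ** 2).sum()

    best = (np.inf, 0.0, 1.0, False)
    thetas = np.linspace(0, 2 * np.pi, 721)
    scales = np.linspace(0.01, 5.0, 500)
    for reflect in (False, True):
        for th in thetas:
            for c in scales:
                v = m2(th, c, reflect)
                if v < best[0]:
                    best = (v, th, c, reflect)
    # local refinement around the grid optimum
    v, th, c, reflect = best
    span_t, span_c = thetas[1] - thetas[0], scales[1] - scales[0]
    for _ in range(refine):
        for th2 in np.linspace(th - span_t, th + span_t, 21):
            for c2 in np.linspace(max(c - span_c, 1e-6), c + span_c, 21):
                v2 = m2(th2, c2, reflect)
                if v2 < v:
                    v, th, c = v2, th2, c2
        span_t /= 8
        span_c /= 8
    return v


def permanova_exhaustive(d2, groups):
    """Pseudo-F over every label permutation; returns (F_obs, p)."""
    groups = np.asarray(groups)
    n = len(groups)
    levels = sorted(set(groups))

    def F(g):
        ss_tot = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for lev in levels:
            idx = np.where(g == lev)[0]
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = ss_tot - ssw
        df1, df2 = len(levels) - 1, n - len(levels)
        return (ssa / df1) / (ssw / df2)

    F_obs = F(groups)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        if perm == tuple(range(n)):
            continue
        total += 1
        if F(groups[list(perm)]) >= F_obs - 1e-12:
            count += 1
    return F_obs, (1 + count) / (1 + total)


def mantel_exhaustive(d1, d2):
    """Pearson r over condensed halves; one-tailed p by full enumeration."""
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)

    def r(mat2):
        return np.corrcoef(d1[iu], mat2[iu])[0, 1]

    r_obs = r(d2)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        if perm == tuple(range(n)):
            continue
        total += 1
        p = list(perm)
        if r(d2[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + total)
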