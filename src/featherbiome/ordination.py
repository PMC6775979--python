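"""Unconstrained ordination and matrix-level permutation tests.

PCoA is the classical Gower double-centred eigendecomposition; NMDS wraps
non-metric SMACOF (Kruskal stress-1) with random restarts plus a PCoA
start; PERMANOVA uses Anderson's distance-based sum-of-squares partition
with free permutation of sample labels; the Mantel test correlates the
condensed halves of two distance matrices under simultaneous row/column
permutation.  Ward clustering of dominant OTUs provides the ordering data
behind composition heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.manifold import smacof

from .containers import DistMatrix, OtuTable, SampleMetadata

__all__ = [
    "PcoaResult",
    "NmdsResult",
    "PermTestResult",
    "pcoa",
    "nmds",
    "permanova",
    "mantel",
    "ward_cluster_heatmap_data",
]

_EIG_TOL = 1e-8


@dataclass
class PcoaResult:
    coords: np.ndarray  # samples x retained axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    prop_explained: np.ndarray  # per retained axis, relative to sum of positives
    labels: list[str] = field(default_factory=list)


def pcoa(d: DistMatrix) -> PcoaResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    Axes with eigenvalue above tolerance are retained; negative
    eigenvalues are reported but never embedded.
    """
    D2 = d.values ** 2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scale = max(abs(w[0]), 1.0) if len(w) else 1.0
    keep = w > _EIG_TOL * scale
    coords = v[:, keep] * np.sqrt(w[keep])
    pos_sum = w[keep].sum()
    prop = w[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    return PcoaResult(coords=coords, eigenvalues=w, prop_explained=prop,
                      labels=list(d.labels))


@dataclass
class NmdsResult:
    coords: np.ndarray
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    labels: list[str] = field(default_factory=list)


def nmds(d: DistMatrix, k: int = 2, n_restarts: int = 8, seed: int = 0,
         max_iter: int = 300) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1, best of several starts.

    Runs ``n_restarts`` random SMACOF starts plus one start from the PCoA
    configuration and returns the lowest-stress solution.
    """
    if d.n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} samples, got {d.n}")
    off = d.condensed()
    if np.allclose(off, off[0]):
        # degenerate: every configuration has the same rank structure
        warnings.warn("all dissimilarities equal; returning flagged zero-stress PCoA")
        base = pcoa(d).coords
        coords = np.zeros((d.n, k))
        m = min(k, base.shape[1])
        coords[:, :m] = base[:, :m]
        return NmdsResult(coords, 0.0, n_restarts, False, list(d.labels))

    best_coords, best_stress = None, np.inf
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray | None] = [None] * n_restarts
    p = pcoa(d).coords
    init = np.zeros((d.n, k))
    m = min(k, p.shape[1])
    init[:, :m] = p[:, :m]
    starts.append(init)
    for st in starts:
        if st is None:
            st = rng.normal(size=(d.n, k))
        coords, stress = smacof(
            d.values, metric=False, n_components=k, init=st, n_init=1,
            max_iter=max_iter, eps=1e-7, random_state=int(rng.integers(2 ** 31)),
            normalized_stress=True,
        )
        if stress < best_stress:
            best_stress, best_coords = stress, coords
    return NmdsResult(best_coords, float(best_stress), n_restarts, True,
                      list(d.labels))


@dataclass
class PermTestResult:
    statistic: float
    p_perm: float
    n_perm: int
    r2: float | None
    seed: int | None


def _group_indicators(groups) -> list[np.ndarray]:
    g = pd.Categorical(groups)
    return [np.asarray(g.codes == c) for c in range(len(g.categories))]


def _permanova_stats(D2: np.ndarray, codes: np.ndarray, n_groups: int,
                     n: int) -> tuple[float, float]:
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for c in range(n_groups):
        mask = codes == c
        n_g = mask.sum()
        if n_g > 1:
            ss_within += D2[np.ix_(mask, mask)][np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    return ss_among, ss_within


def permanova(d: DistMatrix, groups, n_perm: int = 999, seed: int = 0,
              permutations: np.ndarray | None = None) -> PermTestResult:
    """Distance-based multivariate ANOVA (pseudo-F, free label permutation).

    ``permutations`` may supply an explicit (n_perm x n) array of index
    permutations (used for exhaustive enumeration); otherwise ``n_perm``
    random permutations are drawn from ``seed``.
    """
    g = pd.Categorical(groups)
    n = d.n
    if len(g) != n:
        raise ValueError("groups length must match matrix size")
    a = len(g.categories)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = pd.Series(g).value_counts()
    if (sizes == 1).any():
        warnings.warn("groups with a single member present")
    D2 = d.values ** 2
    codes = np.asarray(g.codes)
    ss_among, ss_within = _permanova_stats(D2, codes, a, n)
    df1, df2 = a - 1, n - a
    F_obs = (ss_among / df1) / (ss_within / df2) if ss_within > 0 else np.inf
    r2 = ss_among / (ss_among + ss_within)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
        n_perm = len(permutations)
    count = 0
    for perm in permutations:
        ssa, ssw = _permanova_stats(D2, codes[perm], a, n)
        F_p = (ssa / df1) / (ssw / df2) if ssw > 0 else np.inf
        if F_p >= F_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(float(F_obs), float(p), n_perm, float(r2), seed)


def mantel(d1: DistMatrix, d2: DistMatrix, n_perm: int = 999, seed: int = 0,
           permutations: np.ndarray | None = None) -> PermTestResult:
    """Mantel test: Pearson r between condensed matrices, one-tailed (greater)."""
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if x.std() == 0:
        raise ValueError("zero variance in first distance matrix")
    if d2.values[iu].std() == 0:
        raise ValueError("zero variance in second distance matrix")
    xc = (x - x.mean()) / x.std()

    def corr(yv: np.ndarray) -> float:
        yc = (yv - yv.mean()) / yv.std()
        return float((xc * yc).mean())

    r_obs = corr(d2.values[iu])
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
        n_perm = len(permutations)
    count = 0
    for perm in permutations:
        yp = d2.values[np.ix_(perm, perm)][iu]
        if corr(yp) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(float(r_obs), float(p), n_perm, float(r_obs) ** 2, seed)


def ward_cluster_heatmap_data(
    tab: OtuTable, meta: SampleMetadata, dominance_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Ward (D2) co-clustering data for the dominant-OTU heatmap.

    Dominant OTUs have mean relative abundance >= threshold in at least
    one host species.  Returns (row order over OTUs, column order over
    samples, dominant-OTU relative-abundance matrix OTUs x samples).
    """
    if list(tab.sample_ids) != list(meta.sample_ids):
        raise ValueError("table and metadata must be aligned")
    rel = tab.relative_abundance()
    sp_means = rel.groupby(meta.species.to_numpy()).mean()
    dominant = rel.columns[(sp_means >= dominance_threshold).any(axis=0)]
    if len(dominant) == 0:
        raise ValueError(
            f"no OTU reaches mean relative abundance {dominance_threshold}; "
            "lower dominance_threshold"
        )
    mat = rel[dominant].T  # otus x samples
    def order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] == 1:
            return np.array([0])
        Z = hierarchy.linkage(data, method="ward")
        return np.asarray(hierarchy.leaves_list(Z))
    return order(mat.to_numpy()), order(mat.to_numpy().T), mat


def ward_merge_sequence(points: np.ndarray) -> list[tuple[int, int]]:
    """Ward.D2 merge order (cluster index pairs, scipy convention)."""
    Z = hierarchy.linkage(points, method="ward")
    return [(int(a), int(b)) for a, b in Z[:, :2]]
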