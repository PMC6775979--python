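"""Procrustean cophylogeny (PACo) between host phylogeny and microbiota.

Host cophenetic distances are expanded to sample level (conspecific
samples at distance zero), both distance structures are PCoA-scaled, and
the microbiota configuration is superimposed on the phylogenetic one by
least-squares Procrustes (translation, rotation, scaling).  Significance
of the residual sum of squares m2 comes from permuting whole samples
(rows) of the microbiota configuration; posterior uncertainty in the host
tree is handled by repeating the test over a sample of trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .containers import DistMatrix
from .ordination import pcoa

__all__ = [
    "cophenetic_distance",
    "procrustes_m2",
    "PacoResult",
    "paco_test",
    "paco_over_posterior",
]


def cophenetic_distance(
    tree: dendropy.Tree, sample_species: dict[str, str]
) -> DistMatrix:
    """Sample-level patristic distances via each sample's host species."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    unmapped = sorted(set(sample_species.values()) - set(taxa))
    if unmapped:
        raise ValueError(f"species not in host tree: {unmapped}")
    species = sorted(set(sample_species.values()))
    sp_d = {
        (a, b): (0.0 if a == b else pdm.patristic_distance(taxa[a], taxa[b]))
        for a in species
        for b in species
    }
    samples = sorted(sample_species)
    n = len(samples)
    d = np.zeros((n, n))
    for i, si in enumerate(samples):
        for j in range(i + 1, n):
            v = sp_d[(sample_species[si], sample_species[samples[j]])]
            d[i, j] = d[j, i] = v
    return DistMatrix(samples, d)


def _pad(X: np.ndarray, width: int) -> np.ndarray:
    if X.shape[1] == width:
        return X
    out = np.zeros((X.shape[0], width))
    out[:, : X.shape[1]] = X
    return out


def procrustes_m2(X: np.ndarray, Y: np.ndarray) -> tuple[float, dict]:
    """Least-squares superimposition of Y onto X; residual sum of squares.

    Minimises ||Xc - c * Yc R||^2 over rotation R and scale c after
    centring both configurations; X is the fixed reference.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    width = max(X.shape[1], Y.shape[1])
    Xc = _pad(X, width) - _pad(X, width).mean(axis=0)
    Yc = _pad(Y, width) - _pad(Y, width).mean(axis=0)
    ssx = float((Xc ** 2).sum())
    ssy = float((Yc ** 2).sum())
    if ssy == 0:
        return ssx, {"scale": 0.0, "rotation": np.eye(width)}
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    trace = s.sum()
    scale = trace / ssy
    m2 = ssx - trace ** 2 / ssy
    rotation = U @ Vt
    return float(max(m2, 0.0)), {"scale": float(scale), "rotation": rotation}


@dataclass
class PacoResult:
    m2: float
    p_perm: float
    n_perm: int
    per_tree_m2: list[float] = field(default_factory=list)
    per_tree_p: list[float] = field(default_factory=list)
    seed: int | None = None


def paco_test(
    d_host: DistMatrix,
    d_micro: DistMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PacoResult:
    """PACo permutation test of microbiota dependence on host phylogeny.

    Small m2 indicates co-divergence; p is the fraction of row-permuted
    microbiota configurations achieving m2 at least as small.
    """
    if d_host.labels != d_micro.labels:
        raise ValueError("distance matrices must share labels and order")
    X = pcoa(d_host).coords
    Y = pcoa(d_micro).coords
    width = max(X.shape[1], Y.shape[1])
    Xc = _pad(X, width) - _pad(X, width).mean(axis=0)
    Yc = _pad(Y, width) - _pad(Y, width).mean(axis=0)
    ssx = float((Xc ** 2).sum())
    ssy = float((Yc ** 2).sum())

    def m2_of(Yrows: np.ndarray) -> float:
        Ycc = Yrows - Yrows.mean(axis=0)
        s = np.linalg.svd(Ycc.T @ Xc, compute_uv=False)
        return ssx - s.sum() ** 2 / ssy if ssy > 0 else ssx

    m2_obs = m2_of(Yc)
    rng = np.random.default_rng(seed)
    count = 0
    n = Xc.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if m2_of(Yc[perm]) <= m2_obs + 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PacoResult(m2=float(max(m2_obs, 0.0)), p_perm=float(p), n_perm=n_perm,
                      per_tree_m2=[float(max(m2_obs, 0.0))], per_tree_p=[float(p)],
                      seed=seed)


def paco_over_posterior(
    host_trees: list[dendropy.Tree],
    sample_species: dict[str, str],
    d_micro: DistMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PacoResult:
    """PACo per posterior host tree; pooled m2 = mean, pooled p = median."""
    if not host_trees:
        raise ValueError("need at least one host tree")
    per_m2, per_p = [], []
    rng = np.random.default_rng(seed)
    for tree in host_trees:
        d_host = cophenetic_distance(tree, sample_species).reorder(d_micro.labels)
        res = paco_test(d_host, d_micro, n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        per_m2.append(res.m2)
        per_p.append(res.p_perm)
    return PacoResult(
        m2=float(np.mean(per_m2)),
        p_perm=float(np.median(per_p)),
        n_perm=n_perm,
        per_tree_m2=per_m2,
        per_tree_p=per_p,
        seed=seed,
    )
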