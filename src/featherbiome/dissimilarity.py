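"""Beta-diversity: Bray-Curtis, binary Jaccard and both UniFrac variants.

Bray-Curtis and Jaccard come from scipy's pairwise-distance kernels; the
two UniFrac measures are computed here by classifying every branch of the
rooted bacterial tree by the read mass (or tip presence) descending from
it, vectorised over samples.  Weighted UniFrac is normalised by default so
that it is bounded on [0, 1]; the raw variant is available via a flag.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DistMatrix, OtuTable

__all__ = [
    "bray_curtis",
    "jaccard_binary",
    "unifrac_unweighted",
    "unifrac_weighted",
]


def _check_rows(tab: OtuTable) -> np.ndarray:
    m = tab.matrix.astype(float)
    totals = m.sum(axis=1)
    if (totals == 0).any():
        bad = [tab.sample_ids[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"zero-sum samples: {bad}")
    if len(np.unique(totals)) > 1:
        warnings.warn("unequal sample depths; consider rarefying first")
    return m


def bray_curtis(tab: OtuTable) -> DistMatrix:
    """d(x, y) = sum |x_i - y_i| / sum (x_i + y_i)."""
    m = _check_rows(tab)
    return DistMatrix(tab.sample_ids, squareform(pdist(m, metric="braycurtis")))


def jaccard_binary(tab: OtuTable) -> DistMatrix:
    """1 - |A intersect B| / |A union B| on presence/absence sets."""
    m = _check_rows(tab) > 0
    return DistMatrix(tab.sample_ids, squareform(pdist(m, metric="jaccard")))


def _branch_structure(
    tree: dendropy.Tree, otu_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch (length, descendant-OTU indicator) over all non-root edges.

    OTUs in the table must be tree tips; tree tips absent from the table
    carry no read mass and therefore never contribute.
    """
    tip_index = {}
    for leaf in tree.leaf_node_iter():
        tip_index[leaf.taxon.label] = None
    missing = [o for o in otu_ids if o not in tip_index]
    if missing:
        raise ValueError(f"OTUs absent from bacterial tree: {missing[:5]}...")
    col = {o: j for j, o in enumerate(otu_ids)}

    lengths = []
    rows = []
    # post-order accumulation of descendant-tip indicator vectors
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(len(otu_ids), dtype=bool)
            j = col.get(node.taxon.label)
            if j is not None:
                vec[j] = True
            node._fb_desc = vec
        else:
            node._fb_desc = np.logical_or.reduce(
                [ch._fb_desc for ch in node.child_nodes()]
            )
        if node is not tree.seed_node:
            ln = node.edge.length
            lengths.append(0.0 if ln is None else float(ln))
            rows.append(node._fb_desc)
    lengths = np.asarray(lengths)
    B = np.asarray(rows)
    if lengths.sum() <= 0:
        raise ValueError("tree has zero total branch length; UniFrac undefined")
    return lengths, B


def unifrac_unweighted(tab: OtuTable, tree: dendropy.Tree) -> DistMatrix:
    """Fraction of branch length unique to either sample of a pair."""
    _check_rows(tab)
    lengths, B = _branch_structure(tree, tab.otu_ids)
    present = B @ (tab.matrix > 0).T > 0  # branches x samples
    n = len(tab.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        a = present[:, i]
        both = present[:, i + 1:]
        xor = a[:, None] ^ both
        either = a[:, None] | both
        num = lengths @ xor
        den = lengths @ either
        with np.errstate(invalid="ignore"):
            val = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        d[i, i + 1:] = val
        d[i + 1:, i] = val
    return DistMatrix(tab.sample_ids, d)


def unifrac_weighted(
    tab: OtuTable, tree: dendropy.Tree, normalized: bool = True
) -> DistMatrix:
    """Branch-wise abundance-difference UniFrac.

    raw = sum_b l_b |p_A(b) - p_B(b)| with p(b) the proportion of a
    sample's reads descending from branch b; the normalised variant
    divides by sum_b l_b (p_A(b) + p_B(b)).
    """
    m = _check_rows(tab)
    lengths, B = _branch_structure(tree, tab.otu_ids)
    rel = m / m.sum(axis=1, keepdims=True)
    P = B.astype(float) @ rel.T  # branches x samples
    n = len(tab.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(P[:, [i]] - P[:, i + 1:])
        num = lengths @ diff
        if normalized:
            den = lengths @ (P[:, [i]] + P[:, i + 1:])
            with np.errstate(invalid="ignore"):
                val = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        else:
            val = num
        d[i, i + 1:] = val
        d[i + 1:, i] = val
    return DistMatrix(tab.sample_ids, d)
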