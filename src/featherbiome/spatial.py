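"""Spatially-controlled constrained ordination.

Great-circle sample distances feed PCNM (principal coordinates of
neighbour matrices) spatial eigenfunctions; distance-based RDA regresses
the PCoA axes of a community dissimilarity matrix on predictor terms
(host species dummies, PCNM scores, phylogenetic gradients), testing each
term's marginal effect by Freedman-Lane permutation of reduced-model
residuals.  Forward selection and adjusted-R2 variance partitioning follow
the standard constrained-ordination workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .containers import DistMatrix, SampleMetadata
from .ordination import pcoa

__all__ = [
    "geo_distances",
    "PcnmBasis",
    "pcnm",
    "DbRdaResult",
    "dbrda",
    "forward_select",
    "adjusted_r2",
    "VarpartResult",
    "varpart2",
    "species_dummies",
]

EARTH_RADIUS_KM = 6371.0


def geo_distances(meta: SampleMetadata) -> DistMatrix:
    """Haversine great-circle distances (km) between samples."""
    lat = np.radians(meta.table["lat"].to_numpy(dtype=float))
    lon = np.radians(meta.table["lon"].to_numpy(dtype=float))
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("missing coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistMatrix(meta.sample_ids, d)


@dataclass
class PcnmBasis:
    vectors: np.ndarray  # samples x axes, orthonormal
    eigenvalues: np.ndarray  # positive eigenvalues, decreasing
    truncation_distance: float


def pcnm(d_geo: DistMatrix, truncation: float | None = None) -> PcnmBasis:
    """PCNM spatial eigenfunctions of a (geographic) distance matrix.

    With ``truncation=None`` the threshold is the longest edge of the
    minimum spanning tree; distances above it are replaced by four times
    the threshold before PCoA.  Only positive-eigenvalue axes are kept.
    """
    D = d_geo.values
    n = d_geo.n
    if n < 3:
        raise ValueError("PCNM needs at least 3 locations")
    off = D[np.triu_indices(n, k=1)]
    if np.all(off == 0):
        raise ValueError("all locations identical; PCNM undefined")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    Dmod = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(Dmod, 0.0)
    res = pcoa(DistMatrix(d_geo.labels, Dmod))
    lam = res.eigenvalues[res.eigenvalues > 1e-8 * max(abs(res.eigenvalues[0]), 1.0)]
    vectors = res.coords / np.sqrt(lam)  # back to orthonormal eigenvectors
    return PcnmBasis(vectors=vectors, eigenvalues=lam, truncation_distance=truncation)


# ---------------------------------------------------------------------------
# db-RDA machinery


def _center(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X - X.mean(axis=0)


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    if X.size == 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > 1e-9 * max(s[0], 1.0)).sum()) if len(s) else 0
    return U[:, :rank]


def _check_collinear(terms: dict[str, np.ndarray], n: int) -> None:
    rank_so_far = 0
    X = np.empty((n, 0))
    aliased = []
    for name, cols in terms.items():
        X = np.hstack([X, _center(cols)])
        r = np.linalg.matrix_rank(X)
        if r < rank_so_far + _center(cols).shape[1]:
            aliased.append(name)
        rank_so_far = r
    if aliased:
        raise ValueError(f"collinear (aliased) predictor terms: {aliased}")


@dataclass
class DbRdaResult:
    table: pd.DataFrame  # per term: df, variance, F, p
    residual_variance: float
    residual_df: int
    total_inertia: float
    r2: float
    adj_r2: float


def _response(d: DistMatrix) -> np.ndarray:
    """PCoA coordinates on positive-eigenvalue axes (already centred)."""
    return pcoa(d).coords


def dbrda(
    d: DistMatrix,
    terms: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    response: np.ndarray | None = None,
) -> DbRdaResult:
    """Distance-based RDA with marginal permutation tests per term.

    Each term's marginal F uses SS_full - SS_without-term; significance is
    assessed by Freedman-Lane permutation: residuals of the reduced model
    are permuted, added back to reduced fitted values, and the full model
    re-fitted.  ``terms`` maps term name to its (n x p) design columns.
    """
    Y = _response(d) if response is None else np.asarray(response, dtype=float)
    n = Y.shape[0]
    for name, cols in terms.items():
        if np.asarray(cols).shape[0] != n:
            raise ValueError(f"term {name!r} has wrong number of rows")
    _check_collinear(terms, n)

    total = float((Y ** 2).sum())
    Q_full = _basis(np.hstack([_center(c) for c in terms.values()]))
    m_full = Q_full.shape[1]
    df_res = n - 1 - m_full  # 0 for a saturated model: SS reported, F undefined
    ss_full = float(((Q_full.T @ Y) ** 2).sum()) if m_full else 0.0
    ss_res = total - ss_full
    if df_res == 0:
        n_perm = 0

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)]) if n_perm else None

    rows = []
    for name in terms:
        others = [v for k, v in terms.items() if k != name]
        X_red = (np.hstack([_center(c) for c in others])
                 if others else np.empty((n, 0)))
        Q_red = _basis(X_red)
        m_red = Q_red.shape[1]
        df_t = m_full - m_red
        ss_red = float(((Q_red.T @ Y) ** 2).sum()) if m_red else 0.0
        ss_t = ss_full - ss_red
        F_obs = (
            (ss_t / df_t) / (ss_res / df_res)
            if df_t > 0 and df_res > 0 else np.nan
        )

        if n_perm and df_t > 0:
            fitted_red = Q_red @ (Q_red.T @ Y) if m_red else np.zeros_like(Y)
            E_red = Y - fitted_red
            Yp = fitted_red[None, :, :] + E_red[perms]  # (B, n, k)
            tot_p = (Yp ** 2).sum(axis=(1, 2))
            ss_full_p = ((np.einsum("nm,bnk->bmk", Q_full, Yp)) ** 2).sum(axis=(1, 2))
            ss_red_p = (
                ((np.einsum("nm,bnk->bmk", Q_red, Yp)) ** 2).sum(axis=(1, 2))
                if m_red else np.zeros(n_perm)
            )
            F_p = ((ss_full_p - ss_red_p) / df_t) / ((tot_p - ss_full_p) / df_res)
            p = float((1 + (F_p >= F_obs - 1e-12).sum()) / (1 + n_perm))
        else:
            p = np.nan
        rows.append({"term": name, "df": df_t, "variance": ss_t / (n - 1),
                     "F": F_obs, "p": p})
    rows.append({"term": "Residual", "df": df_res,
                 "variance": ss_res / (n - 1), "F": np.nan, "p": np.nan})
    r2 = ss_full / total if total > 0 else 0.0
    return DbRdaResult(
        table=pd.DataFrame(rows).set_index("term"),
        residual_variance=ss_res / (n - 1),
        residual_df=df_res,
        total_inertia=total / (n - 1),
        r2=float(r2),
        adj_r2=adjusted_r2(float(r2), n, m_full) if df_res > 0 else np.nan,
    )


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - r2)(n - 1)/(n - m - 1)."""
    if n - m - 1 < 1:
        raise ValueError(f"insufficient degrees of freedom (n={n}, m={m})")
    return float(1 - (1 - r2) * (n - 1) / (n - m - 1))


def _model_r2(Y: np.ndarray, terms: dict[str, np.ndarray]) -> tuple[float, int]:
    if not terms:
        return 0.0, 0
    Q = _basis(np.hstack([_center(c) for c in terms.values()]))
    total = float((Y ** 2).sum())
    ss = float(((Q.T @ Y) ** 2).sum())
    return (ss / total if total > 0 else 0.0), Q.shape[1]


def forward_select(
    d: DistMatrix,
    candidates: dict[str, np.ndarray],
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
    adj_r2_cap: bool = True,
) -> list[str]:
    """Greedy forward selection of db-RDA predictor terms.

    At each step the candidate with the smallest Freedman-Lane permutation
    p-value (ties: larger adjusted-R2 gain) is added; selection stops when
    the best p exceeds ``alpha`` or when the selected set's adjusted R2
    would exceed that of the full candidate model (double stopping rule).
    """
    Y = _response(d)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    full_r2, full_m = _model_r2(Y, candidates)
    full_adj = adjusted_r2(full_r2, n, full_m)
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        best = None
        for name in remaining:
            terms = {k: candidates[k] for k in selected + [name]}
            sub_seed = int(rng.integers(2 ** 31))
            res = dbrda(d, terms, n_perm=n_perm, seed=sub_seed, response=Y)
            p = res.table.loc[name, "p"]
            r2_new, m_new = _model_r2(Y, terms)
            adj_new = adjusted_r2(r2_new, n, m_new)
            key = (p, -adj_new)
            if best is None or key < best[0]:
                best = (key, name, adj_new)
        (p_best, _), name_best, adj_best = best
        if p_best > alpha:
            break
        # small tolerance: with near-perfect fits a lone true predictor can
        # exceed the full-model adjusted R2 by a numerical sliver, which
        # must not abort the selection
        if adj_r2_cap and adj_best > full_adj + 1e-3:
            break
        selected.append(name_best)
        remaining.remove(name_best)
    return selected


@dataclass
class VarpartResult:
    a: float  # pure set1
    b: float  # shared
    c: float  # pure set2
    d: float  # residual
    adj_set1: float
    adj_set2: float
    adj_union: float


def varpart2(
    d: DistMatrix,
    set1: dict[str, np.ndarray],
    set2: dict[str, np.ndarray],
) -> VarpartResult:
    """Two-set variance partitioning on adjusted R2 (vegan varpart logic)."""
    if not set1 or not set2:
        raise ValueError("both predictor sets must be nonempty")
    Y = _response(d)
    n = Y.shape[0]

    def adj(terms: dict[str, np.ndarray]) -> float:
        r2, m = _model_r2(Y, terms)
        return adjusted_r2(r2, n, m)

    adj1 = adj(set1)
    adj2 = adj(set2)
    union = dict(set1)
    for k, v in set2.items():
        key = k if k not in union else f"{k}__set2"
        union[key] = v
    adj_u = adj(union)  # rank-based m, so aliased duplicates cost nothing
    a = adj_u - adj2
    c = adj_u - adj1
    b = adj1 + adj2 - adj_u
    resid = 1 - adj_u
    return VarpartResult(a=a, b=b, c=c, d=resid,
                         adj_set1=adj1, adj_set2=adj2, adj_union=adj_u)


def species_dummies(species: pd.Series | np.ndarray) -> np.ndarray:
    """Treatment-coded dummy matrix (first level dropped)."""
    g = pd.Categorical(species)
    dummies = pd.get_dummies(pd.Series(g)).to_numpy(dtype=float)
    return dummies[:, 1:]
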