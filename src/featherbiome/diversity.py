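"""Alpha diversity: rarefaction normalisation, Shannon index, one-way ANOVA.

Samples are rarefied once (a single random subsample without replacement,
seed logged by the caller) to the minimum sequencing depth, after which
Shannon diversity (natural log) and observed OTU richness are computed and
compared among host species with a classical one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable

__all__ = ["rarefy", "shannon", "alpha_diversity", "one_way_anova", "AnovaResult"]


def rarefy(tab: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Raises ``ValueError`` listing the offending samples if any sample has
    fewer than ``depth`` reads.  Deterministic for a given seed.
    """
    totals = tab.counts.sum(axis=1)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise ValueError(
            f"samples shallower than depth {depth}: {shallow} "
            f"(totals {totals[shallow].tolist()})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(tab.matrix)
    for i, row in enumerate(tab.matrix):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(pd.DataFrame(out, index=tab.counts.index, columns=tab.counts.columns))


def shannon(counts: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over nonzero categories."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    if (c < 0).any():
        raise ValueError("negative counts")
    p = c[c > 0] / c.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(tab: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and observed OTU richness."""
    mat = tab.matrix
    return pd.DataFrame(
        {
            "shannon": [shannon(row) for row in mat],
            "observed_otus": (mat > 0).sum(axis=1),
        },
        index=tab.counts.index,
    )


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    r2: float


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA with R2 = SS_between / SS_total."""
    y = np.asarray(values, dtype=float)
    g = pd.Categorical(groups)
    if len(y) != len(g):
        raise ValueError("values and groups differ in length")
    levels = g.categories
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    grand = y.mean()
    ssb = 0.0
    ssw = 0.0
    for lev in levels:
        yi = y[np.asarray(g == lev)]
        if len(yi) == 0:
            raise ValueError(f"empty group {lev!r}")
        ssb += len(yi) * (yi.mean() - grand) ** 2
        ssw += ((yi - yi.mean()) ** 2).sum()
    df1 = len(levels) - 1
    df2 = len(y) - len(levels)
    if df2 < 1:
        raise ValueError("residual degrees of freedom < 1")
    if ssw == 0:
        warnings.warn("zero within-group variance; p reported as 0-limit")
        return AnovaResult(F=np.inf, df1=df1, df2=df2, p=0.0, r2=1.0)
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    r2 = ssb / (ssb + ssw)
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p, r2=float(r2))
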