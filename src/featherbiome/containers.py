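"""Shared domain containers for feather-microbiota analyses.

All downstream stages operate on these types; file parsing lives in
:mod:`featherbiome.io`.  Invariants are enforced at construction so that a
malformed object can never propagate into an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "SeqSet",
    "TreeSet",
    "DistMatrix",
]


class FormatError(ValueError):
    """A file or object violates a format invariant."""


@dataclass
class OtuTable:
    """Non-negative integer read counts, samples in rows, OTUs in columns.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix indexed by sample id with OTU ids as columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in OTU table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate OTU ids in OTU table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("non-integer counts in OTU table")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            bad = np.argwhere(df.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[bad[0]]!r}, "
                f"OTU {df.columns[bad[1]]!r}"
            )
        if (df.sum(axis=1) == 0).any():
            empty = df.index[df.sum(axis=1) == 0].tolist()
            raise FormatError(f"samples with zero total reads: {empty}")
        object.__setattr__(self, "counts", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        m = self.counts.to_numpy(dtype=float)
        return pd.DataFrame(
            m / m.sum(axis=1, keepdims=True),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def sorted(self) -> "OtuTable":
        """Return a copy with samples sorted by id (reproducible ordering)."""
        return OtuTable(self.counts.sort_index())


@dataclass
class SampleMetadata:
    """Per-sample host species, sampling locality and coordinates."""

    table: pd.DataFrame  # index sample_id; columns species, locality, lat, lon

    REQUIRED = ("species", "locality", "lat", "lon")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        lat = df["lat"].to_numpy(dtype=float)
        lon = df["lon"].to_numpy(dtype=float)
        if np.any((lat < -90) | (lat > 90)):
            raise FormatError("latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise FormatError("longitude outside [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> pd.Series:
        return self.table["species"]

    def sorted(self) -> "SampleMetadata":
        return SampleMetadata(self.table.sort_index())


_DNA = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class SeqSet:
    """Ordered mapping of sequence id to an upper-case DNA string.

    IUPAC ambiguity codes are tolerated on construction (readers accept
    them); alignment-based operations reject them explicitly.
    """

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        for sid, s in self.seqs.items():
            if not s:
                raise FormatError(f"empty sequence {sid!r}")
            up = s.upper()
            bad = set(up) - _IUPAC
            if bad:
                raise FormatError(f"sequence {sid!r}: invalid characters {sorted(bad)}")
            self.seqs[sid] = up

    def __len__(self) -> int:
        return len(self.seqs)

    def __getitem__(self, sid: str) -> str:
        return self.seqs[sid]

    def __iter__(self):
        return iter(self.seqs)

    def items(self):
        return self.seqs.items()

    def is_unambiguous(self, sid: str) -> bool:
        return set(self.seqs[sid]) <= _DNA


@dataclass
class TreeSet:
    """A rooted bacterial tree plus a posterior sample of host species trees."""

    bacterial_tree: dendropy.Tree | None = None
    host_trees: list[dendropy.Tree] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.host_trees:
            tipsets = [
                frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                for t in self.host_trees
            ]
            if len(set(tipsets)) > 1:
                raise FormatError("host trees do not share an identical tip set")


@dataclass
class DistMatrix:
    """Symmetric, hollow, non-negative pairwise dissimilarity matrix."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if len(set(self.labels)) != n:
            raise FormatError("duplicate labels in distance matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise FormatError("distance matrix not symmetric")
        v = (v + v.T) / 2.0
        if np.any(np.diag(v) != 0):
            if not np.allclose(np.diag(v), 0, atol=1e-10):
                raise FormatError("distance matrix diagonal not zero")
            np.fill_diagonal(v, 0.0)
        if (v < 0).any():
            raise FormatError("negative dissimilarity")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", list(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: list[str]) -> "DistMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def reorder(self, labels: list[str]) -> "DistMatrix":
        if set(labels) != set(self.labels):
            raise FormatError("reorder labels must be a permutation of existing labels")
        return self.submatrix(list(labels))
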