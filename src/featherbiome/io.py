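"""Readers and writers for the plain-text formats used throughout.

OTU tables and distance matrices are square/rectangular TSV, metadata is
CSV, sequences are FASTA (via Biopython) and trees are newick (via
dendropy, one tree per line for multi-tree files).  Sample ordering is
fixed at load time (sorted by sample id) so that permutation seeds are
reproducible across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DistMatrix, FormatError, OtuTable, SampleMetadata, SeqSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_dist_matrix",
    "write_dist_matrix",
    "align_table_metadata",
]


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a samples x OTUs TSV count table (header = OTU ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{path}: non-numeric cell in OTU table")
        frac = np.mod(arr.astype(float), 1)
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise FormatError(
                f"{path}: non-integer count at row {df.index[i]!r}, col {df.columns[j]!r}"
            )
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"{path}: negative count at row {df.index[i]!r}, col {df.columns[j]!r}"
            )
        tab = OtuTable(df.astype(np.int64))
    except FormatError:
        raise
    return tab.sorted()


def write_otu_table(tab: OtuTable, path: str | Path) -> None:
    tab.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df).sorted()


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, index_label="sample_id")


def read_fasta(path: str | Path) -> SeqSet:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return SeqSet(seqs)


def write_fasta(seqs: SeqSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _check_lengths(tree: dendropy.Tree, where: str) -> None:
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise FormatError(f"{where}: negative branch length")
    if n_missing:
        logger.warning("%s: %d missing branch lengths set to 0", where, n_missing)


def read_newick(path: str | Path):
    """Read one tree, or a list of trees for multi-line files."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    trees = []
    for i, ln in enumerate(lines):
        if ln.count("(") != ln.count(")"):
            raise FormatError(
                f"{path}, tree {i + 1}: unbalanced parentheses "
                f"({ln.count('(')} open vs {ln.count(')')} close)"
            )
        tree = dendropy.Tree.get(
            data=ln, schema="newick", rooting="force-rooted",
            preserve_underscores=True,
        )
        _check_lengths(tree, f"{path} tree {i + 1}")
        trees.append(tree)
    if not trees:
        raise FormatError(f"{path}: no trees found")
    return trees[0] if len(trees) == 1 else trees


def write_newick(trees, path: str | Path) -> None:
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def read_dist_matrix(path: str | Path) -> DistMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise FormatError(f"{path}: row and column labels differ")
    return DistMatrix(labels, df.to_numpy(dtype=float))


def write_dist_matrix(d: DistMatrix, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
            fh, sep="\t", index_label="id"
        )


def align_table_metadata(
    tab: OtuTable, meta: SampleMetadata
) -> tuple[OtuTable, SampleMetadata]:
    """Restrict both objects to their shared samples, identically ordered."""
    shared = sorted(set(tab.sample_ids) & set(meta.sample_ids))
    if not shared:
        raise FormatError("OTU table and metadata share no sample ids")
    dropped = (set(tab.sample_ids) | set(meta.sample_ids)) - set(shared)
    if dropped:
        logger.warning("align_table_metadata: dropping samples %s", sorted(dropped))
    return (
        OtuTable(tab.counts.loc[shared]),
        SampleMetadata(meta.table.loc[shared]),
    )
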