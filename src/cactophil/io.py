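"""Readers and writers for the pipeline's file formats.

FASTA through Biopython, newick through the :class:`SpeciesTree` wrapper
(dendropy underneath), OBO v1.2 through obonet (is_a edges only, cycles
rejected), and tab-separated tables through pandas.  Malformed records
raise with file and reason; write -> read round-trips are identities.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import SpeciesTree

__all__ = [
    "read_fasta", "write_fasta",
    "read_tree", "write_tree",
    "read_obo", "read_tsv", "write_tsv",
    "GENE_TABLE_COLUMNS", "SIMILARITY_COLUMNS", "SELECTION_COLUMNS",
    "sha256_of",
]

GENE_TABLE_COLUMNS = ["gene_id", "species", "scaffold", "order_index", "strand"]
SIMILARITY_COLUMNS = ["gene_a", "gene_b", "score"]
SELECTION_COLUMNS = ["gene_id", "branch", "selected"]


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_tree(path: str | Path) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text())


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_obo(source: str | Path | _io.StringIO) -> nx.MultiDiGraph:
    """OBO v1.2 ontology as an obonet graph; cyclic ontologies rejected."""
    graph = obonet.read_obo(source)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{source}: ontology contains a cycle")
    return graph


def read_tsv(
    path: str | Path, required: list[str] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
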