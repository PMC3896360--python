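"""Readers and writers for the external formats the toolkit speaks.

FASTA (proteomes and alignments) goes through Biopython; distance matrices use
the relaxed PHYLIP square dialect (full whitespace-delimited labels); trees are
Newick via scikit-bio.  FASTA headers for proteomes encode ``species_id|gene``
with a configurable delimiter; a one-file-per-species layout (species id taken
from the file stem) is also accepted.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

from .model import (
    DEFAULT_STRIP,
    Proteome,
    ProteinRecord,
    SpeciesTable,
    gene_sort_key,
    sanitize_sequence,
)


# ---------------------------------------------------------------------------
# species table


def read_species_table(path: str | os.PathLike) -> SpeciesTable:
    """Read a 2-3 column TSV (species_id, phylum[, class]); header required."""
    rows: list[tuple[str, str, str | None]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty species table")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            cls = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
            rows.append((parts[0].strip(), parts[1].strip(), cls))
    return SpeciesTable(rows)


def write_species_table(table: SpeciesTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tphylum\tclass\n")
        for sid, phylum, cls in table.rows:
            fh.write(f"{sid}\t{phylum}\t{cls or ''}\n")


# ---------------------------------------------------------------------------
# proteomes


def read_proteomes(
    fasta_paths: Sequence[str | os.PathLike],
    table: SpeciesTable,
    delimiter: str = "|",
    strip: frozenset[str] = DEFAULT_STRIP,
) -> list[Proteome]:
    """Read multi-FASTA proteome files into one :class:`Proteome` per species.

    Headers are ``species_id<delimiter>gene_name``.  Headers without the
    delimiter are interpreted as gene names in a one-species-per-file layout,
    with the species id taken from the file stem.  Species are ordered by the
    metadata table, genes canonically within each species.
    """
    by_species: dict[str, list[ProteinRecord]] = {}
    for path in fasta_paths:
        stem = Path(path).stem
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if delimiter in header:
                sid, gene = header.split(delimiter, 1)
            else:
                sid, gene = stem, header
            if sid not in table:
                raise ValueError(
                    f"{path}: header {header!r}: unknown species id {sid!r}"
                )
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"{path}: header {header!r}: empty sequence")
            by_species.setdefault(sid, []).append(
                ProteinRecord(gene, sanitize_sequence(seq, strip))
            )
    proteomes = []
    for sid in sorted(by_species, key=table.order):
        proteins = sorted(by_species[sid], key=lambda p: gene_sort_key(p.gene_name))
        proteomes.append(
            Proteome(
                species_id=sid,
                proteins=proteins,
                phylum=table.phylum(sid),
                class_label=table.class_label(sid),
            )
        )
    return proteomes


def write_proteomes(
    proteomes: Iterable[Proteome],
    path: str | os.PathLike,
    delimiter: str = "|",
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for pr in proteomes:
            for rec in pr.proteins:
                fh.write(f">{pr.species_id}{delimiter}{rec.gene_name}\n")
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# distance matrices (relaxed PHYLIP square)


def write_distance_matrix(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    data = np.asarray(dm.data)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, data):
            fh.write(label + "  " + "  ".join(f"{v:.9f}" for v in row) + "\n")


def read_distance_matrix(path: str | os.PathLike) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(rows)}")
    return DistanceMatrix(np.array(rows), labels)


# ---------------------------------------------------------------------------
# trees


def write_newick(
    tree: TreeNode, path: str | os.PathLike, with_support: bool = False
) -> None:
    """Write *tree* as Newick; optionally render ``node.support`` values
    (percentages) as internal node labels."""
    leaves = [t.name for t in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")
    out = tree.copy()
    if with_support:
        for node in out.non_tips(include_self=False):
            support = getattr(node, "support", None)
            if support is not None:
                node.name = f"{support:g}"
    out.write(str(path), format="newick")


def read_newick(path: str | os.PathLike) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path: str | os.PathLike):
    """Read an aligned FASTA into a :class:`~keystrings.conservation.Alignment`."""
    from .conservation import Alignment

    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment.from_rows(ids, rows)


def write_alignment(aln, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.row_strings()):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
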