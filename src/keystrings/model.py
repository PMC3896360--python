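"""Shared domain model: proteomes, species metadata, and sequence sanitation.

A *proteome* here is one species' set of mitochondrial protein-coding gene
products (typically the 13 metazoan mt genes: atp6, atp8, cox1-3, nad1-6,
nad4L, cob) together with its taxonomic labels.  All downstream K-string
counting treats each protein independently, so protein boundaries are part of
the model and never crossed by a sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetically ordered.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Residue codes silently dropped during sanitation.  Ambiguity codes and the
#: stop marker can never match a K-string over the 20-letter alphabet, so
#: removing them only shortens the window count.
DEFAULT_STRIP = frozenset("BZJX*")

#: Canonical metazoan mitochondrial gene order used for deterministic output.
CANONICAL_GENE_ORDER = (
    "atp6", "atp8", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L",
    "nad5", "nad6", "cob",
)
_GENE_RANK = {g: i for i, g in enumerate(CANONICAL_GENE_ORDER)}


class SanitationError(ValueError):
    """Raised when a sequence contains residues outside the sanitation policy."""


def sanitize_sequence(seq: str, strip: frozenset[str] = DEFAULT_STRIP) -> str:
    """Upper-case *seq*, drop strippable codes, and reject anything else.

    Raises
    ------
    SanitationError
        If residues remain that are neither canonical nor strippable, or the
        sequence becomes empty.
    """
    up = seq.upper()
    cleaned = []
    dropped = 0
    bad: set[str] = set()
    for ch in up:
        if ch in AMINO_ACID_SET:
            cleaned.append(ch)
        elif ch in strip:
            dropped += 1
        else:
            bad.add(ch)
    if bad:
        raise SanitationError(
            "non-canonical residues outside sanitation policy: "
            + ", ".join(repr(c) for c in sorted(bad))
        )
    if dropped:
        log.debug("sanitation dropped %d ambiguous residue(s)", dropped)
    out = "".join(cleaned)
    if not out:
        raise SanitationError("sequence empty after sanitation")
    return out


def gene_sort_key(name: str) -> tuple[int, str]:
    """Canonical mt gene order first, unknown genes lexicographically after."""
    return (_GENE_RANK.get(name, len(CANONICAL_GENE_ORDER)), name)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein-coding gene product."""

    gene_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for gene {self.gene_name!r}")
        extra = set(self.sequence) - AMINO_ACID_SET
        if extra:
            raise ValueError(
                f"gene {self.gene_name!r}: non-canonical residues "
                f"{sorted(extra)}; sanitize first"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """One species' ordered collection of protein records."""

    species_id: str
    proteins: list[ProteinRecord]
    display_name: str = ""
    phylum: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.species_id!r} has no proteins")
        names = [p.gene_name for p in self.proteins]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"proteome {self.species_id!r}: duplicate gene names {dup}"
            )

    @property
    def gene_names(self) -> list[str]:
        return [p.gene_name for p in self.proteins]

    @property
    def total_length(self) -> int:
        return sum(len(p) for p in self.proteins)

    def sorted_canonically(self) -> "Proteome":
        return Proteome(
            species_id=self.species_id,
            proteins=sorted(self.proteins, key=lambda p: gene_sort_key(p.gene_name)),
            display_name=self.display_name,
            phylum=self.phylum,
            class_label=self.class_label,
        )


@dataclass
class SpeciesTable:
    """species_id -> (phylum, optional class) metadata, in file order."""

    rows: list[tuple[str, str, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate species ids in table: {dup}")
        self._index = {r[0]: i for i, r in enumerate(self.rows)}

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def __len__(self) -> int:
        return len(self.rows)

    def order(self, species_id: str) -> int:
        return self._index[species_id]

    def phylum(self, species_id: str) -> str:
        return self.rows[self._index[species_id]][1]

    def class_label(self, species_id: str) -> str | None:
        return self.rows[self._index[species_id]][2]

    @property
    def species_ids(self) -> list[str]:
        return [r[0] for r in self.rows]
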