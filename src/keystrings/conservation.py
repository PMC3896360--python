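"""Sliding-window conservativity and key-string localization on alignments.

Conservativity of an alignment window is driven by the multiplicity m of its
most frequent row segment: ``score = round(scale * (m - 1) / (n - 1))`` on an
integer 0..scale scale (default 15), so identical windows across all n rows
score the maximum and all-distinct windows score 0.  Gap characters count as
ordinary symbols.  Key K-strings are mapped back onto (possibly gapped) rows
as per-column occurrence coverage; contiguous well-covered column runs are
*accumulation regions*, whose conservativity is contrasted against the rest
of the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .keys import KeySet

GAP = "-"


@dataclass
class Alignment:
    """n aligned rows over residues plus '-', as an (n, L) char matrix."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-d")
        if self.matrix.shape[0] < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids/matrix row mismatch")

    @classmethod
    def from_rows(cls, ids: list[str], rows: list[str]) -> "Alignment":
        if len(rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        matrix = np.array([list(r) for r in rows], dtype="<U1")
        return cls(ids=list(ids), matrix=matrix)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def row_strings(self) -> list[str]:
        return ["".join(r) for r in self.matrix]


@dataclass
class ConservationProfile:
    """Integer conservativity per window start (1-based columns)."""

    window: int
    step: int
    scale: int
    L: int
    scores: dict[int, int]

    def column_scores(self) -> np.ndarray:
        """Per-column conservativity: the max over windows covering each
        column (0 where no window covers)."""
        out = np.zeros(self.L, dtype=int)
        for start, sc in self.scores.items():
            i = start - 1
            j = min(i + self.window, self.L)
            np.maximum(out[i:j], sc, out=out[i:j])
        return out


def conservativity_profile(
    aln: Alignment, window: int = 5, step: int = 1, scale: int = 15
) -> ConservationProfile:
    """Slide a window over the alignment and score each position."""
    if aln.L < window:
        raise ValueError(f"alignment length {aln.L} < window {window}")
    rows = aln.row_strings()
    n = aln.n
    scores: dict[int, int] = {}
    for i in range(0, aln.L - window + 1, step):
        segs = Counter(r[i : i + window] for r in rows)
        m = max(segs.values())
        # half-up rounding: round() would take 7.5 -> 8 but 6.5 -> 6
        scores[i + 1] = int(np.floor(scale * (m - 1) / (n - 1) + 0.5))
    return ConservationProfile(window=window, step=step, scale=scale,
                               L=aln.L, scores=scores)


def map_keys(sequence: str, keys: KeySet) -> np.ndarray:
    """Per-position key-string coverage of one sequence or alignment row.

    Gap characters are skipped for matching; coverage is reported on the
    original (possibly gapped) coordinate system, so rows taken from an
    alignment yield alignment-column coverage.  Overlapping occurrences all
    count.
    """
    cols = [i for i, ch in enumerate(sequence) if ch != GAP]
    ungapped = "".join(sequence[i] for i in cols)
    coverage = np.zeros(len(sequence), dtype=int)
    K = keys.K
    for key in keys.strings:
        start = ungapped.find(key)
        while start != -1:
            for off in range(K):
                coverage[cols[start + off]] += 1
            start = ungapped.find(key, start + 1)
    return coverage


@dataclass
class AccumulationRegion:
    """1-based inclusive alignment-column interval of dense key coverage."""

    start: int
    end: int
    hit_density: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def accumulation_regions(
    coverages: list[np.ndarray], min_total: int = 1, min_len: int = 5
) -> list[AccumulationRegion]:
    """Maximal column runs where summed coverage >= min_total for >= min_len
    consecutive columns."""
    lengths = {len(c) for c in coverages}
    if len(lengths) != 1:
        raise ValueError("coverage vectors have unequal lengths")
    total = np.sum(np.vstack(coverages), axis=0)
    mask = total >= min_total
    regions: list[AccumulationRegion] = []
    i = 0
    L = len(total)
    while i < L:
        if mask[i]:
            j = i
            while j + 1 < L and mask[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                regions.append(
                    AccumulationRegion(
                        start=i + 1,
                        end=j + 1,
                        hit_density=float(total[i : j + 1].mean()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions


def regions_to_bed(regions: list[AccumulationRegion], path, label: str = "aln") -> None:
    """BED-like export: half-open 0-based intervals."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{label}\t{r.start - 1}\t{r.end}\t{r.hit_density:.3f}\n")


def overlap_summary(
    regions: list[AccumulationRegion],
    prof: ConservationProfile,
    conserved_cutoff: int = 8,
) -> dict[str, float | None]:
    """Fraction of region vs non-region columns whose best covering window
    scores strictly above the cutoff."""
    col = prof.column_scores()
    in_region = np.zeros(prof.L, dtype=bool)
    for r in regions:
        in_region[r.start - 1 : r.end] = True
    conserved = col > conserved_cutoff
    n_in = int(in_region.sum())
    n_out = prof.L - n_in
    return {
        "region_conserved_fraction": (
            float(conserved[in_region].mean()) if n_in else None
        ),
        "background_conserved_fraction": (
            float(conserved[~in_region].mean()) if n_out else None
        ),
        "n_region_columns": float(n_in),
        "n_background_columns": float(n_out),
    }
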