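"""Composition profiles of key sets and the chi-square frequency-bias test.

The composition profile tallies residue patterns over a key set: single
residues, contiguous dimers, gap-1 dimers (positions i and i+2), or
contiguous triplets.  The chi-square test asks whether observed K-string
counts in a proteome deviate from their order-(K-2) Markov expectations:
``X^2 = sum (O - E)^2 / E`` over the k tested strings, compared against a
chi-square with k - 1 degrees of freedom at the 5% level.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cv import count_kstrings, markov_expected
from .keys import KeySet
from .model import Proteome

log = logging.getLogger(__name__)

MODES = ("mono", "dimer", "gapped_dimer", "triplet")


@dataclass
class CompositionProfile:
    mode: str
    frequencies: dict[str, float]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pattern\tfrequency\n")
            for pat in sorted(self.frequencies):
                fh.write(f"{pat}\t{self.frequencies[pat]:.10g}\n")


def _patterns(s: str, mode: str):
    if mode == "mono":
        yield from s
    elif mode == "dimer":
        for i in range(len(s) - 1):
            yield s[i : i + 2]
    elif mode == "gapped_dimer":
        for i in range(len(s) - 2):
            yield s[i] + s[i + 2]
    elif mode == "triplet":
        for i in range(len(s) - 2):
            yield s[i : i + 3]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def composition_profile(keys: KeySet, mode: str = "mono") -> CompositionProfile:
    """Pattern frequencies over all positions of a key set."""
    if not keys.strings:
        raise ValueError("empty key set")
    tally: Counter[str] = Counter()
    for s in keys.strings:
        tally.update(_patterns(s, mode))
    total = sum(tally.values())
    return CompositionProfile(
        mode=mode, frequencies={p: c / total for p, c in tally.items()}
    )


@dataclass
class ChiSquareResult:
    statistic: float
    k: int
    dof: int
    p_value: float
    significant_at_5pct: bool


def chi_square_from_counts(
    observed: np.ndarray, expected: np.ndarray
) -> ChiSquareResult:
    """Pearson X^2 over matched observed/expected counts, dof = k - 1."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape or O.ndim != 1:
        raise ValueError("observed and expected must be 1-d and matched")
    if len(O) < 2:
        raise ValueError("need at least 2 categories")
    if np.any(E <= 0):
        raise ValueError("expected counts must be positive")
    x2 = float(np.sum((O - E) ** 2 / E))
    dof = len(O) - 1
    p = float(stats.chi2.sf(x2, dof))
    return ChiSquareResult(x2, len(O), dof, p, p < 0.05)


def chi_square_test(
    proteome: Proteome, K: int, strings: "set[str] | frozenset[str] | list[str]"
) -> ChiSquareResult:
    """Observed vs Markov-expected counts of the given K-strings.

    Strings with zero expectation are dropped with a warning (k adjusted).
    """
    tested = sorted(set(strings))
    cK = count_kstrings(proteome, K)
    cKm1 = count_kstrings(proteome, K - 1)
    cKm2 = count_kstrings(proteome, K - 2)
    O, E, kept = [], [], []
    for s in tested:
        if len(s) != K:
            raise ValueError(f"string {s!r} does not have length {K}")
        e = cK.total_windows * markov_expected(cK, cKm1, cKm2, s)
        if e <= 0:
            log.warning("string %s has zero expectation; dropped", s)
            continue
        kept.append(s)
        O.append(cK.counts.get(s, 0))
        E.append(e)
    if len(kept) < 2:
        raise ValueError("fewer than 2 testable strings after dropping E=0")
    return chi_square_from_counts(np.array(O), np.array(E))
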