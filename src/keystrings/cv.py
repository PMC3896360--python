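"""K-string counting and Markov-background-subtracted composition vectors.

For a species' proteome, the frequency ``p(s)`` of every length-K peptide
(window step 1, never crossing a protein boundary) is compared against the
prediction of an order-(K-2) Markov model built from the same proteome's
(K-1)- and (K-2)-string frequencies::

    p0(a1..aK) = p(a1..a(K-1)) * p(a2..aK) / p(a2..a(K-1))

Each frequency is normalized by its own order's total window count.  The
composition-vector entry is the relative deviation ``(p - p0) / p0`` (0 by
convention when ``p0`` is 0).  Entries are defined for every string with
``p > 0`` or ``p0 > 0``; all others are implicitly 0, so vectors are sparse.

A scikit-learn compatible :class:`CompositionVectorizer` exposes the same
computation as a transformer producing a sparse matrix over a learned
K-string vocabulary; the functional helpers wrap it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .model import Proteome


@dataclass
class KStringCounts:
    """Sliding-window counts of all observed length-K peptides."""

    K: int
    counts: dict[str, int]
    total_windows: int

    def frequency(self, s: str) -> float:
        if self.total_windows == 0:
            return 0.0
        return self.counts.get(s, 0) / self.total_windows


@dataclass
class CompositionVector:
    """Sparse background-subtracted composition vector for one species."""

    K: int
    scores: dict[str, float]
    species_id: str = ""

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, s: str, default: float = 0.0) -> float:
        return self.scores.get(s, default)

    def project(self, keys: "set[str] | frozenset[str]") -> "CompositionVector":
        """Restrict to the given key strings (absent keys stay 0)."""
        return CompositionVector(
            K=self.K,
            scores={s: v for s, v in self.scores.items() if s in keys},
            species_id=self.species_id,
        )


def count_kstrings(proteome: Proteome, K: int) -> KStringCounts:
    """Count length-K windows (step 1) within each protein independently."""
    if K < 1:
        raise ValueError("K must be >= 1")
    counter: Counter[str] = Counter()
    total = 0
    for rec in proteome.proteins:
        seq = rec.sequence
        n = len(seq) - K + 1
        if n <= 0:
            continue
        total += n
        for i in range(n):
            counter[seq[i : i + K]] += 1
    if total == 0:
        raise ValueError(
            f"proteome {proteome.species_id!r}: no countable windows at K={K}"
        )
    return KStringCounts(K=K, counts=dict(counter), total_windows=total)


def substring_frequencies(proteome: Proteome, k_sub: int) -> KStringCounts:
    """Counts at a shorter order, needed by the Markov background."""
    return count_kstrings(proteome, k_sub)


def markov_expected(
    cK: KStringCounts, cKm1: KStringCounts, cKm2: KStringCounts, s: str
) -> float:
    """Order-(K-2) Markov prediction ``p0(s)`` from lower-order frequencies.

    Returns 0 when the core ``s[1:-1]`` was never observed.
    """
    if len(s) != cK.K:
        raise ValueError(f"string {s!r} does not have length {cK.K}")
    core = s[1:-1]
    p_core = cKm2.frequency(core)
    if p_core == 0.0:
        return 0.0
    return cKm1.frequency(s[:-1]) * cKm1.frequency(s[1:]) / p_core


def _cv_scores(proteome: Proteome, K: int) -> dict[str, float]:
    """Sparse ``(p-p0)/p0`` scores over every string with p>0 or p0>0.

    The support of p0 is exactly the set of joins ``w1 + w2[-1]`` over
    observed (K-1)-mers w1, w2 with ``w1[1:] == w2[:-1]``; every observed
    K-mer is such a join, so no separate pass over ``p`` is needed.
    """
    cK = count_kstrings(proteome, K)
    cKm1 = count_kstrings(proteome, K - 1)
    cKm2 = count_kstrings(proteome, K - 2)

    by_prefix: dict[str, list[str]] = {}
    for w in cKm1.counts:
        by_prefix.setdefault(w[: K - 2], []).append(w)

    wK, wKm1, wKm2 = cK.total_windows, cKm1.total_windows, cKm2.total_windows
    scores: dict[str, float] = {}
    for w1, n1 in cKm1.counts.items():
        core = w1[1:]
        partners = by_prefix.get(core)
        if not partners:
            continue
        n_core = cKm2.counts[core]
        for w2 in partners:
            s = w1 + w2[-1]
            p0 = (n1 / wKm1) * (cKm1.counts[w2] / wKm1) / (n_core / wKm2)
            p = cK.counts.get(s, 0) / wK
            score = (p - p0) / p0
            if score != 0.0:
                scores[s] = score
    return scores


def composition_vector(proteome: Proteome, K: int = 5) -> CompositionVector:
    """Build one species' composition vector."""
    if K < 3:
        raise ValueError("K must be >= 3 (the background model needs K-2 >= 1)")
    return CompositionVector(
        K=K, scores=_cv_scores(proteome, K), species_id=proteome.species_id
    )


def cv_matrix(proteomes: list[Proteome], K: int = 5) -> list[CompositionVector]:
    """One composition vector per species, in input order."""
    ids = [p.species_id for p in proteomes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate species ids: {dup}")
    return [composition_vector(p, K) for p in proteomes]


def vectors_to_sparse(
    rows: list[CompositionVector], vocabulary: list[str] | None = None
) -> tuple[sp.csr_matrix, list[str]]:
    """Stack sparse composition vectors into a CSR matrix.

    The vocabulary defaults to the sorted union of supports; strings absent
    from a row contribute an implicit 0.
    """
    if vocabulary is None:
        vocab_set: set[str] = set()
        for r in rows:
            vocab_set.update(r.scores)
        vocabulary = sorted(vocab_set)
    index = {s: j for j, s in enumerate(vocabulary)}
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for r in rows:
        for s, v in r.scores.items():
            j = index.get(s)
            if j is not None:
                indices.append(j)
                data.append(v)
        indptr.append(len(data))
    X = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(len(rows), len(vocabulary)),
    )
    X.sum_duplicates()
    X.sort_indices()
    return X, list(vocabulary)


class CompositionVectorizer(TransformerMixin, BaseEstimator):
    """Turn proteomes into a sparse composition-vector matrix.

    Parameters
    ----------
    k : int, default 5
        K-string length (3-7 are sensible; 5 is the standard choice).

    Attributes
    ----------
    vocabulary_ : list of str
        Sorted union of the K-strings supporting the fitted proteomes.
    species_ids_ : list of str
        Row labels, in fit order.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X: list[Proteome], y=None):
        rows = cv_matrix(list(X), self.k)
        vocab: set[str] = set()
        for r in rows:
            vocab.update(r.scores)
        self.vocabulary_ = sorted(vocab)
        self.species_ids_ = [p.species_id for p in X]
        self._fit_rows = rows
        return self

    def transform(self, X: list[Proteome]) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("CompositionVectorizer is not fitted")
        rows = cv_matrix(list(X), self.k)
        M, _ = vectors_to_sparse(rows, self.vocabulary_)
        return M

    def fit_transform(self, X: list[Proteome], y=None) -> sp.csr_matrix:
        self.fit(X)
        M, _ = vectors_to_sparse(self._fit_rows, self.vocabulary_)
        return M

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.vocabulary_, dtype=object)


def export_cv_tsv(proteome: Proteome, K: int, path) -> None:
    """Write one species' K-strings with p, p0 and score columns."""
    cK = count_kstrings(proteome, K)
    cKm1 = count_kstrings(proteome, K - 1)
    cKm2 = count_kstrings(proteome, K - 2)
    cvec = composition_vector(proteome, K)
    strings = sorted(set(cK.counts) | set(cvec.scores))
    with open(path, "w") as fh:
        fh.write("kstring\tp\tp0\tscore\n")
        for s in strings:
            p = cK.frequency(s)
            p0 = markov_expected(cK, cKm1, cKm2, s)
            fh.write(f"{s}\t{p:.10g}\t{p0:.10g}\t{cvec.get(s):.10g}\n")
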