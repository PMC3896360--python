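"""Variance-based dimensional reduction: extracting key K-strings.

Across a group of N species, each K-string (column of the composition-vector
matrix) gets the population variance of its N scores (absent entries count as
0).  Sorted variances form an L-shaped curve; the corner is operationalized as
a 90% reduction of the maximum variance, i.e. threshold ``0.1 * v_max``, and
the strings strictly above it are the *key K-strings* — the small feature
subset that carries the tree-building signal.

Three flavours mirror the extraction protocol:

* group keys: species are shuffled into near-equal subgroups, keys are
  selected per subgroup, and the subgroup sets are intersected;
* broad keys: the group procedure is repeated on random species samples until
  newly found keys are almost all already known; the per-repetition sets are
  intersected (core) and unioned (broad);
* taxon-specific keys: the group procedure inside each subtaxon (e.g. class),
  unioned with the broad set;
* global keys: the union of all taxon-specific and broad sets.

:class:`KeyStringSelector` packages the variance thresholding as a
scikit-learn feature selector over any sparse score matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .cv import CompositionVector, cv_matrix
from .model import Proteome

log = logging.getLogger(__name__)

DEFAULT_REDUCTION = 0.90


@dataclass
class VarianceProfile:
    """Per-K-string score variance across a species group."""

    K: int
    variances: dict[str, float]
    n_species: int
    reduction: float = DEFAULT_REDUCTION

    @property
    def v_max(self) -> float:
        return max(self.variances.values(), default=0.0)

    @property
    def critical_value(self) -> float:
        return (1.0 - self.reduction) * self.v_max

    def sorted_variances(self) -> np.ndarray:
        """Descending variances — the L-curve ordinates."""
        return np.sort(np.fromiter(self.variances.values(), dtype=float))[::-1]


@dataclass
class KeySet:
    """A named set of key K-strings with extraction provenance."""

    K: int
    strings: frozenset[str]
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.strings)

    def __contains__(self, s: str) -> bool:
        return s in self.strings

    def union(self, *others: "KeySet", label: str = "union") -> "KeySet":
        strings = frozenset().union(self.strings, *(o.strings for o in others))
        return KeySet(
            K=self.K,
            strings=strings,
            label=label,
            provenance={"parents": [self.label] + [o.label for o in others]},
        )

    def intersection(self, *others: "KeySet", label: str = "intersection") -> "KeySet":
        strings = self.strings.intersection(*(o.strings for o in others))
        return KeySet(
            K=self.K,
            strings=strings,
            label=label,
            provenance={"parents": [self.label] + [o.label for o in others]},
        )


def write_keyset(ks: KeySet, path) -> None:
    """One K-string per line; '#' header lines carry provenance."""
    with open(path, "w") as fh:
        fh.write(f"# label={ks.label} K={ks.K} n={len(ks)}\n")
        for k, v in sorted(ks.provenance.items()):
            fh.write(f"# {k}={v}\n")
        for s in sorted(ks.strings):
            fh.write(s + "\n")


def read_keyset(path) -> KeySet:
    strings = []
    label = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "label=" in line:
                    label = line.split("label=")[1].split()[0]
                continue
            strings.append(line)
    if not strings:
        return KeySet(K=0, strings=frozenset(), label=label)
    K = len(strings[0])
    if any(len(s) != K for s in strings):
        raise ValueError(f"{path}: mixed string lengths")
    return KeySet(K=K, strings=frozenset(strings), label=label)


# ---------------------------------------------------------------------------
# variance profile and threshold


def variance_profile(
    rows: list[CompositionVector], reduction: float = DEFAULT_REDUCTION
) -> VarianceProfile:
    """Population variance of each K-string's scores across the group.

    Strings absent from every row are not stored (their variance is 0).
    """
    if len(rows) < 2:
        raise ValueError("variance needs at least 2 species")
    Ks = {r.K for r in rows}
    if len(Ks) != 1:
        raise ValueError(f"mixed K among rows: {sorted(Ks)}")
    n = len(rows)
    sums: dict[str, float] = {}
    sumsq: dict[str, float] = {}
    for r in rows:
        for s, v in r.scores.items():
            sums[s] = sums.get(s, 0.0) + v
            sumsq[s] = sumsq.get(s, 0.0) + v * v
    variances = {
        s: max(sumsq[s] / n - (sums[s] / n) ** 2, 0.0) for s in sums
    }
    return VarianceProfile(
        K=Ks.pop(), variances=variances, n_species=n, reduction=reduction
    )


def critical_point(vp: VarianceProfile, reduction: float | None = None) -> float:
    """L-curve corner: ``(1 - reduction) * v_max`` (0.1 * v_max by default)."""
    r = vp.reduction if reduction is None else reduction
    if not (0.0 < r < 1.0):
        raise ValueError("reduction must be in (0, 1)")
    return (1.0 - r) * vp.v_max


def select_keys(
    vp: VarianceProfile, reduction: float | None = None, label: str = "keys"
) -> KeySet:
    """Strings with variance strictly above the critical point."""
    thr = critical_point(vp, reduction)
    strings = frozenset(s for s, v in vp.variances.items() if v > thr)
    return KeySet(
        K=vp.K,
        strings=strings,
        label=label,
        provenance={
            "n_species": vp.n_species,
            "v_max": vp.v_max,
            "critical_value": thr,
        },
    )


# ---------------------------------------------------------------------------
# extraction protocols


def effective_subgroups(n_pool: int, n_clades: int, requested: int = 5) -> int:
    """Scale the subgroup count so each subgroup can represent every clade.

    The subgroup intersection only retains a clade-diagnostic string when
    every subgroup contains both carriers and non-carriers, so subgroups
    should hold at least ~2 species per clade.  With large pools this
    returns *requested*; with small ones it shrinks (never below 1).
    """
    if n_pool < 2:
        raise ValueError("need >= 2 species")
    by_size = max(1, n_pool // max(2 * n_clades, 4))
    return max(1, min(requested, by_size, n_pool // 2))


def _partition(ids: list[int], n_subgroups: int, rng: np.random.Generator):
    """Seeded shuffle then round-robin; remainders land in the earliest
    subgroups."""
    order = list(ids)
    rng.shuffle(order)
    groups: list[list[int]] = [[] for _ in range(n_subgroups)]
    for i, sid in enumerate(order):
        groups[i % n_subgroups].append(sid)
    return groups


def extract_group_keys(
    proteomes: list[Proteome],
    K: int = 5,
    n_subgroups: int = 5,
    reduction: float = DEFAULT_REDUCTION,
    seed: int | np.random.Generator = 0,
    rows: list[CompositionVector] | None = None,
    label: str = "group",
) -> KeySet:
    """Intersection of per-subgroup key sets over a random near-equal split.

    Precomputed composition vectors may be passed via *rows* (same order as
    *proteomes*) to avoid recounting.
    """
    n = len(proteomes)
    if n_subgroups < 1:
        raise ValueError("n_subgroups must be >= 1")
    if n < 2 * n_subgroups:
        raise ValueError(
            f"need >= {2 * n_subgroups} species for {n_subgroups} subgroups, got {n}"
        )
    rng = np.random.default_rng(seed)
    if rows is None:
        rows = cv_matrix(proteomes, K)
    if n_subgroups == 1:
        vp = variance_profile(rows, reduction)
        ks = select_keys(vp, label=label)
        ks.provenance["subgroups"] = [[p.species_id for p in proteomes]]
        return ks
    groups = _partition(list(range(n)), n_subgroups, rng)
    sets = []
    for g in groups:
        vp = variance_profile([rows[i] for i in g], reduction)
        sets.append(select_keys(vp))
    keys = sets[0].intersection(*sets[1:], label=label)
    keys.provenance["subgroups"] = [
        [proteomes[i].species_id for i in g] for g in groups
    ]
    return keys


def extract_broad_keys(
    proteomes: list[Proteome],
    K: int = 5,
    group_size: int = 20,
    n_subgroups: int = 5,
    max_reps: int = 10,
    convergence: float = 0.95,
    reduction: float = DEFAULT_REDUCTION,
    seed: int | np.random.Generator = 0,
    rows: list[CompositionVector] | None = None,
) -> tuple[KeySet, KeySet, list[KeySet]]:
    """Repeat the group extraction on random species samples to convergence.

    Returns ``(core, broad, groups)``: the intersection and union over the
    per-repetition key sets, plus the sets themselves.  The loop stops when a
    new repetition's keys are at least *convergence* contained in the running
    union, or after *max_reps* repetitions.
    """
    n = len(proteomes)
    if group_size < 2 * n_subgroups:
        raise ValueError("group_size must be >= 2 * n_subgroups")
    if n < group_size:
        raise ValueError(f"need >= {group_size} species, got {n}")
    rng = np.random.default_rng(seed)
    if rows is None:
        rows = cv_matrix(proteomes, K)
    union: set[str] = set()
    groups: list[KeySet] = []
    for rep in range(1, max_reps + 1):
        pick = rng.choice(n, size=group_size, replace=False)
        sub_p = [proteomes[i] for i in pick]
        sub_r = [rows[i] for i in pick]
        ks = extract_group_keys(
            sub_p,
            K=K,
            n_subgroups=n_subgroups,
            reduction=reduction,
            seed=rng,
            rows=sub_r,
            label=f"rep{rep}",
        )
        groups.append(ks)
        new = ks.strings
        containment = 1.0 if not new else len(new & union) / len(new)
        union |= new
        if rep >= 2 and containment >= convergence:
            log.info("broad extraction converged at repetition %d", rep)
            break
    core = groups[0].intersection(*groups[1:], label="core")
    broad = groups[0].union(*groups[1:], label="broad")
    prov = {
        "n_reps": len(groups),
        "group_size": group_size,
        "n_subgroups": n_subgroups,
        "convergence": convergence,
    }
    core.provenance.update(prov)
    broad.provenance.update(prov)
    return core, broad, groups


def extract_specific_keys(
    proteomes: list[Proteome],
    K: int = 5,
    subtaxon_of=None,
    broad: KeySet | None = None,
    n_subgroups: int = 5,
    reduction: float = DEFAULT_REDUCTION,
    seed: int | np.random.Generator = 0,
    rows: list[CompositionVector] | None = None,
    label: str = "specific",
) -> KeySet:
    """Taxon-specific keys: per-subtaxon group extraction, unioned with the
    broad set.

    *subtaxon_of* maps species_id to a subtaxon label; defaults to each
    proteome's ``class_label`` (species without one form a single pool).
    Subtaxa too small to split use adaptive subgrouping
    (``n_subgroups = min(requested, n // 2)``); below 4 species the whole
    subtaxon's variance profile is used directly; below 2, it is skipped.
    """
    rng = np.random.default_rng(seed)
    if rows is None:
        rows = cv_matrix(proteomes, K)
    if subtaxon_of is None:
        subtaxon_of = {
            p.species_id: (p.class_label or "_all") for p in proteomes
        }
    by_sub: dict[str, list[int]] = {}
    for i, p in enumerate(proteomes):
        by_sub.setdefault(subtaxon_of[p.species_id], []).append(i)

    sets: list[KeySet] = []
    for sub in sorted(by_sub):
        idx = by_sub[sub]
        if len(idx) < 2:
            log.warning("subtaxon %r has <2 species; skipped", sub)
            continue
        sub_rows = [rows[i] for i in idx]
        if len(idx) < 4:
            vp = variance_profile(sub_rows, reduction)
            sets.append(select_keys(vp, label=f"{label}:{sub}"))
        else:
            eff = min(n_subgroups, len(idx) // 2)
            sets.append(
                extract_group_keys(
                    [proteomes[i] for i in idx],
                    K=K,
                    n_subgroups=eff,
                    reduction=reduction,
                    seed=rng,
                    rows=sub_rows,
                    label=f"{label}:{sub}",
                )
            )
    parents = sets + ([broad] if broad is not None else [])
    if not parents:
        raise ValueError("no subtaxon had >= 2 species")
    out = parents[0].union(*parents[1:], label=label) if len(parents) > 1 else parents[0]
    return KeySet(K=out.K, strings=out.strings, label=label,
                  provenance={"subtaxa": sorted(by_sub),
                              "with_broad": broad is not None})


def global_keys(per_taxon: list[KeySet], broad: KeySet | None = None) -> KeySet:
    """Union of all taxon-specific sets and the broad set."""
    sets = list(per_taxon) + ([broad] if broad is not None else [])
    if not sets:
        raise ValueError("no key sets given")
    out = sets[0].union(*sets[1:], label="global") if len(sets) > 1 else sets[0]
    return KeySet(
        K=out.K,
        strings=out.strings,
        label="global",
        provenance={"parents": [s.label for s in sets]},
    )


# ---------------------------------------------------------------------------
# sharing / bias statistics


@dataclass
class SharingTable:
    """Pairwise key-set sharing: sizes, shared counts, and bias percentages.

    ``bias[i][j]`` (for i != j) is ``100 * (1 - shared(i,j) / size(j))`` —
    the percentage of column taxon j's keys absent from taxon i — rounded to
    one decimal; None when the column set is empty.
    """

    labels: list[str]
    sizes: list[int]
    shared: np.ndarray  # symmetric, diagonal = sizes
    bias: list[list[float | None]]

    @classmethod
    def from_counts(
        cls, labels: list[str], sizes: list[int], shared: np.ndarray
    ) -> "SharingTable":
        shared = np.asarray(shared, dtype=float)
        n = len(labels)
        bias: list[list[float | None]] = [[None] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    bias[i][j] = 0.0
                elif sizes[j] > 0:
                    bias[i][j] = round(100.0 * (1.0 - shared[i, j] / sizes[j]), 1)
        return cls(labels=labels, sizes=list(sizes), shared=shared, bias=bias)

    def to_tsv(self, path) -> None:
        """Mirror the published layout: diagonal sizes, shared counts above,
        bias percentages below."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = []
                for j in range(len(self.labels)):
                    if i == j:
                        cells.append(str(self.sizes[i]))
                    elif j > i:
                        cells.append(str(int(self.shared[i, j])))
                    else:
                        b = self.bias[i][j]
                        cells.append("" if b is None else f"{b:.1f}")
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


def sharing_table(sets: list[KeySet]) -> SharingTable:
    """Pairwise sharing statistics over >=2 key sets of the same K."""
    if len(sets) < 2:
        raise ValueError("need >= 2 key sets")
    Ks = {s.K for s in sets}
    if len(Ks) != 1:
        raise ValueError(f"mixed K among key sets: {sorted(Ks)}")
    n = len(sets)
    labels = [s.label or f"set{i}" for i, s in enumerate(sets)]
    sizes = [len(s) for s in sets]
    shared = np.zeros((n, n))
    for i in range(n):
        shared[i, i] = sizes[i]
        for j in range(i + 1, n):
            shared[i, j] = shared[j, i] = len(sets[i].strings & sets[j].strings)
    return SharingTable.from_counts(labels, sizes, shared)


def summarize_sharing(st: SharingTable) -> dict[str, float]:
    """Min/max/mean of the diagonal, the shared counts, and the bias cells."""
    n = len(st.labels)
    up = [st.shared[i, j] for i in range(n) for j in range(i + 1, n)]
    lo = [
        st.bias[i][j]
        for i in range(n)
        for j in range(i)
        if st.bias[i][j] is not None
    ]
    out: dict[str, float] = {
        "size_min": float(min(st.sizes)),
        "size_max": float(max(st.sizes)),
        "size_mean": float(np.mean(st.sizes)),
    }
    if up:
        out.update(
            shared_min=float(min(up)),
            shared_max=float(max(up)),
            shared_mean=float(np.mean(up)),
        )
    if lo:
        out.update(
            bias_min=float(min(lo)),
            bias_max=float(max(lo)),
            bias_mean=float(np.mean(lo)),
        )
    return out


# ---------------------------------------------------------------------------
# sklearn-style selector


class KeyStringSelector(SelectorMixin, BaseEstimator):
    """Variance-threshold feature selection with an L-curve corner threshold.

    Selects the columns of a (sparse) score matrix whose population variance
    strictly exceeds ``(1 - reduction) * max(variance)``.  Composes with
    :class:`~keystrings.cv.CompositionVectorizer` in a sklearn pipeline.
    """

    def __init__(self, reduction: float = DEFAULT_REDUCTION):
        self.reduction = reduction

    def fit(self, X, y=None):
        if not (0.0 < self.reduction < 1.0):
            raise ValueError("reduction must be in (0, 1)")
        X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        if X.shape[0] < 2:
            raise ValueError("variance needs at least 2 rows")
        n = X.shape[0]
        mean = np.asarray(X.mean(axis=0)).ravel()
        meansq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        self.variances_ = np.maximum(meansq - mean**2, 0.0)
        self.v_max_ = float(self.variances_.max(initial=0.0))
        self.threshold_ = (1.0 - self.reduction) * self.v_max_
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        if not hasattr(self, "variances_"):
            raise ValueError("KeyStringSelector is not fitted")
        return self.variances_ > self.threshold_
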