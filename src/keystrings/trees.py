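"""Distance-based tree construction and comparison.

Species are compared by the cosine of the angle between their composition
vectors, ``C(A,B)``, turned into a distance ``D = (1 - C) / 2`` in [0, 1].
Trees come from neighbor joining (scikit-bio's Saitou-Nei implementation with
negative branch lengths clamped to zero).  Branch support uses a gene-family
bootstrap: whole mitochondrial gene families are drawn with replacement, the
same draw applied to every species so the composition vectors stay
comparable, and each internal edge of the full-data tree is annotated with
the percentage of replicate trees containing the same leaf bipartition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import majority_rule as _majority_rule
from skbio.tree import nj as _nj

from .cv import CompositionVector, cv_matrix
from .keys import KeySet
from .model import Proteome, ProteinRecord

log = logging.getLogger(__name__)


@dataclass
class BootstrapPlan:
    """Gene-family resampling plan for branch support."""

    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# distances


def cosine_distance(
    a: CompositionVector, b: CompositionVector, keys: KeySet | None = None
) -> float:
    """``(1 - C) / 2`` over the union of supports; 0.5 when a projected
    vector is all-zero (C defined as 0)."""
    if a.K != b.K:
        raise ValueError(f"K mismatch: {a.K} vs {b.K}")
    sa, sb = a.scores, b.scores
    if keys is not None:
        ks = keys.strings
        sa = {s: v for s, v in sa.items() if s in ks}
        sb = {s: v for s, v in sb.items() if s in ks}
    na = math.sqrt(sum(v * v for v in sa.values()))
    nb = math.sqrt(sum(v * v for v in sb.values()))
    if na == 0.0 or nb == 0.0:
        if na == 0.0 and nb == 0.0 and a.species_id == b.species_id:
            return 0.0
        log.debug(
            "all-zero projected vector (%s vs %s); distance set to 0.5",
            a.species_id, b.species_id,
        )
        return 0.5
    small, large = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    dot = sum(v * large.get(s, 0.0) for s, v in small.items())
    c = dot / (na * nb)
    d = (1.0 - c) / 2.0
    return min(max(d, 0.0), 1.0)


def distance_matrix(
    rows: list[CompositionVector], keys: KeySet | None = None
) -> DistanceMatrix:
    """Symmetric zero-diagonal cosine distance matrix over all species."""
    n = len(rows)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            data[i, j] = data[j, i] = cosine_distance(rows[i], rows[j], keys)
    return DistanceMatrix(data, [r.species_id for r in rows])


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Unrooted neighbor-joining tree (negative branch lengths clamped)."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    return _nj(dm, neg_as_zero=True)


# ---------------------------------------------------------------------------
# bipartitions and topology comparison


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial leaf bipartitions of an (un)rooted tree.

    Each internal edge splits the leaves in two; splits are normalized as a
    frozenset of the two sides so rooted and unrooted encodings of the same
    topology compare equal.
    """
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return splits


@dataclass
class TopologyComparison:
    similarity_pct: float
    rf: int
    n_shared: int
    n_splits_1: int
    n_splits_2: int


def compare_topologies(t1: TreeNode, t2: TreeNode) -> TopologyComparison:
    """Shared-bipartition similarity and Robinson-Foulds distance."""
    l1 = frozenset(t.name for t in t1.tips())
    l2 = frozenset(t.name for t in t2.tips())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    shared = b1 & b2
    denom = max(len(b1), len(b2))
    sim = 100.0 if denom == 0 else 100.0 * len(shared) / denom
    rf = len(b1 ^ b2)
    return TopologyComparison(sim, rf, len(shared), len(b1), len(b2))


def topology_similarity(t1: TreeNode, t2: TreeNode) -> float:
    return compare_topologies(t1, t2).similarity_pct


def taxa_monophyletic(tree: TreeNode, taxon_of: dict[str, str]) -> dict[str, bool]:
    """Whether each taxon's leaves form a clade (an unrooted bipartition)."""
    splits = bipartitions(tree)
    all_leaves = frozenset(t.name for t in tree.tips())
    out: dict[str, bool] = {}
    for taxon in sorted(set(taxon_of.values())):
        side = frozenset(l for l in all_leaves if taxon_of[l] == taxon)
        if len(side) in (1, len(all_leaves)):
            out[taxon] = True
        else:
            out[taxon] = frozenset({side, all_leaves - side}) in splits
    return out


def induced_taxon_tree(tree: TreeNode, taxon_of: dict[str, str]) -> TreeNode:
    """Collapse the tree to one leaf per taxon (lexicographically first
    species represents its taxon; only meaningful when taxa are clades)."""
    reps: dict[str, str] = {}
    for leaf in sorted(t.name for t in tree.tips()):
        reps.setdefault(taxon_of[leaf], leaf)
    sub = tree.copy().shear(sorted(reps.values()))
    for tip in sub.tips():
        tip.name = taxon_of[tip.name]
    return sub


# ---------------------------------------------------------------------------
# bootstrap


def resample_gene_draw(universe: list[str], rng: np.random.Generator) -> list[str]:
    """Draw ``len(universe)`` gene families with replacement (one locus
    bootstrap draw, applied identically to every species)."""
    idx = rng.integers(0, len(universe), size=len(universe))
    return [universe[i] for i in idx]


def _resample_proteome(p: Proteome, draw: list[str]) -> Proteome | None:
    by_gene = {rec.gene_name: rec for rec in p.proteins}
    proteins = []
    for k, g in enumerate(draw):
        rec = by_gene.get(g)
        if rec is not None:
            # suffix keeps gene names unique when a family is drawn twice
            proteins.append(ProteinRecord(f"{g}#{k}", rec.sequence))
    if not proteins:
        return None
    return Proteome(
        species_id=p.species_id,
        proteins=proteins,
        phylum=p.phylum,
        class_label=p.class_label,
    )


def bootstrap_trees(
    proteomes: list[Proteome],
    plan: BootstrapPlan,
    K: int = 5,
    keys: KeySet | None = None,
) -> list[TreeNode]:
    """Rebuild the full counting/CV/distance/NJ chain per gene-family draw."""
    universe = sorted({g for p in proteomes for g in p.gene_names})
    if not universe:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(plan.seed)
    trees: list[TreeNode] = []
    for _ in range(plan.n_replicates):
        draw = resample_gene_draw(universe, rng)
        rep = [_resample_proteome(p, draw) for p in proteomes]
        if any(r is None for r in rep):
            dropped = [p.species_id for p, r in zip(proteomes, rep) if r is None]
            raise ValueError(
                f"replicate draw left species without proteins: {dropped}"
            )
        rows = cv_matrix(rep, K)
        trees.append(nj_tree(distance_matrix(rows, keys)))
    return trees


def consensus_support(main: TreeNode, replicates: list[TreeNode]) -> TreeNode:
    """Annotate each internal edge of *main* with the percentage of
    replicates containing the same leaf bipartition (``node.support``)."""
    if not replicates:
        raise ValueError("no replicate trees")
    counts: dict[frozenset[frozenset[str]], int] = {}
    for t in replicates:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    out = main.copy()
    all_leaves = frozenset(t.name for t in out.tips())
    n = len(all_leaves)
    for node in out.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            split = frozenset({side, all_leaves - side})
            node.support = 100.0 * counts.get(split, 0) / len(replicates)
    return out


def majority_rule_consensus(
    replicates: list[TreeNode], cutoff: float = 0.5
) -> TreeNode:
    """Majority-rule consensus of the replicate trees (scikit-bio)."""
    trees = _majority_rule([t.copy() for t in replicates], cutoff=cutoff)
    if isinstance(trees, list):
        if len(trees) != 1:
            raise ValueError(
                "replicates do not share one leaf set; got "
                f"{len(trees)} consensus components"
            )
        return trees[0]
    return trees
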