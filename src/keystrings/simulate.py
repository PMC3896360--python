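"""Clade-structured synthetic mitochondrial-like proteomes with ground truth.

The generator draws a random root proteome and evolves it down a known clade
tree (balanced over phyla, caterpillar within each phylum, unit branch
lengths) by per-site substitution with a uniform replacement residue.
Engineered features provide controllable signal:

* conserved blocks: contiguous gene intervals evolving at ``rate *
  multiplier`` (multiplier <= 1), emulating the slowly evolving cores of
  mitochondrial proteins;
* diagnostic motifs: length-K strings overwritten into the ancestor of a
  chosen clade (a phylum or a deeper clade) and held invariant below it.
  Each motif must sit fully inside a conserved block — diagnostic variants
  embedded in conserved cores, which is what makes key K-strings accumulate
  in conserved regions;
* context strings: for each motif, copies of its interior (K-2)-core with
  neutral flanks are written into conserved blocks of the root (hence all
  species) and held invariant.  Without them a single-copy motif is
  invisible to the composition vector: a string whose prefix, suffix and
  core counts all equal its own count has p == p0 and scores 0.  A common
  core with clade-unique flanks gives carriers a score of roughly the number
  of context copies, and non-carriers no entry at all.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .conservation import Alignment
from .model import AMINO_ACIDS, Proteome, ProteinRecord, SpeciesTable

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Mitochondrial-realistic protein lengths (aa), canonical gene order.
DEFAULT_GENES: tuple[tuple[str, int], ...] = (
    ("atp6", 226), ("atp8", 55), ("cox1", 513), ("cox2", 227), ("cox3", 261),
    ("nad1", 318), ("nad2", 347), ("nad3", 115), ("nad4", 459), ("nad4L", 98),
    ("nad5", 603), ("nad6", 174), ("cob", 380),
)


@dataclass(frozen=True)
class Motif:
    """A diagnostic K-string written into one clade's ancestor.

    ``clade`` is a tuple of phylum names whose most recent common ancestor
    receives the motif; ``position`` is 1-based within ``gene``.
    """

    clade: tuple[str, ...]
    gene: str
    position: int
    motif: str


@dataclass
class SimulationConfig:
    n_phyla: int = 4
    species_per_phylum: int = 5
    genes: tuple[tuple[str, int], ...] = DEFAULT_GENES
    substitution_rate: float = 0.05
    conserved_blocks: tuple[tuple[str, int, int, float], ...] = ()
    motifs: tuple[Motif, ...] = ()
    context_copies: int = 10
    seed: int = 0

    @property
    def phylum_names(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_phyla)]

    def validate(self) -> None:
        errors: list[str] = []
        lengths = dict(self.genes)
        if self.n_phyla < 1 or self.species_per_phylum < 1:
            errors.append("need >= 1 phylum and >= 1 species per phylum")
        if not (0.0 <= self.substitution_rate <= 1.0):
            errors.append("substitution_rate must be in [0, 1]")
        occupied: dict[str, list[tuple[int, int]]] = {}
        for gene, start, end, mult in self.conserved_blocks:
            if gene not in lengths:
                errors.append(f"block references unknown gene {gene!r}")
                continue
            if not (1 <= start <= end <= lengths[gene]):
                errors.append(f"block {gene}:{start}-{end} outside gene bounds")
            if not (0.0 <= mult <= 1.0):
                errors.append(f"block {gene}:{start}-{end}: multiplier not in [0,1]")
            for s0, e0 in occupied.get(gene, []):
                if start <= e0 and s0 <= end:
                    errors.append(f"overlapping blocks in gene {gene}")
            occupied.setdefault(gene, []).append((start, end))
        phyla = set(self.phylum_names)
        motif_spans: dict[str, list[tuple[int, int]]] = {}
        for m in self.motifs:
            if not set(m.clade) <= phyla:
                errors.append(f"motif clade {m.clade} has unknown phyla")
            if set(m.motif) - set(AMINO_ACIDS):
                errors.append(f"motif {m.motif!r} has non-canonical residues")
            if m.gene not in lengths:
                errors.append(f"motif references unknown gene {m.gene!r}")
                continue
            lo, hi = m.position, m.position + len(m.motif) - 1
            if not (1 <= lo <= hi <= lengths[m.gene]):
                errors.append(f"motif {m.motif} at {m.gene}:{lo} outside gene")
            inside = any(
                s <= lo and hi <= e
                for g, s, e, _ in self.conserved_blocks
                if g == m.gene
            )
            partial = any(
                (lo <= e and s <= hi) and not (s <= lo and hi <= e)
                for g, s, e, _ in self.conserved_blocks
                if g == m.gene
            )
            if partial:
                errors.append(
                    f"motif {m.motif} at {m.gene}:{lo} partially overlaps a "
                    "conserved block"
                )
            elif not inside:
                errors.append(
                    f"motif {m.motif} at {m.gene}:{lo} must lie inside a "
                    "conserved block"
                )
            for s0, e0 in motif_spans.get(m.gene, []):
                if lo <= e0 and s0 <= hi:
                    errors.append(f"overlapping motifs in gene {m.gene}")
            motif_spans.setdefault(m.gene, []).append((lo, hi))
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    tree: TreeNode
    phylum_of: dict[str, str]
    motifs: list[Motif]
    motif_species: dict[str, list[str]]  # motif string -> carrier species ids
    blocks: tuple[tuple[str, int, int, float], ...]
    genes: tuple[tuple[str, int], ...]
    context_sites: list[tuple[str, int, int]]  # gene, start, end (1-based)

    def gene_offset(self, gene: str) -> int:
        """0-based offset of *gene* in the concatenated coordinate system."""
        off = 0
        for g, length in self.genes:
            if g == gene:
                return off
            off += length
        raise KeyError(gene)

    def block_columns(self) -> list[tuple[int, int]]:
        """Conserved blocks as 1-based inclusive concatenated columns."""
        return [
            (self.gene_offset(g) + s, self.gene_offset(g) + e)
            for g, s, e, _ in self.blocks
        ]

    def motif_columns(self) -> dict[str, tuple[int, int]]:
        return {
            m.motif: (
                self.gene_offset(m.gene) + m.position,
                self.gene_offset(m.gene) + m.position + len(m.motif) - 1,
            )
            for m in self.motifs
        }

    def phylum_tree(self) -> TreeNode:
        """The induced tree over phylum labels."""
        t = self.tree.copy()
        # keep one representative tip per phylum, then relabel
        phyla = sorted(set(self.phylum_of.values()))
        reps = {}
        for tip in t.tips():
            ph = self.phylum_of[tip.name]
            reps.setdefault(ph, tip.name)
        sheared = t.shear([reps[ph] for ph in phyla])
        for tip in sheared.tips():
            tip.name = self.phylum_of[tip.name]
        return sheared


def _balanced_tree(labels: list[str]) -> TreeNode:
    if len(labels) == 1:
        return TreeNode(name=labels[0], length=1.0)
    mid = (len(labels) + 1) // 2
    node = TreeNode(length=1.0)
    node.extend([_balanced_tree(labels[:mid]), _balanced_tree(labels[mid:])])
    return node


def _caterpillar(labels: list[str]) -> TreeNode:
    node = TreeNode(name=labels[0], length=1.0)
    if len(labels) == 1:
        return node
    parent = TreeNode(length=1.0)
    parent.extend([node, _caterpillar(labels[1:])])
    return parent


def build_true_tree(config: SimulationConfig) -> TreeNode:
    """Balanced phylum backbone, caterpillar within each phylum, unit
    branch lengths."""
    subtrees = []
    for ph in config.phylum_names:
        species = [f"{ph}_s{i + 1}" for i in range(config.species_per_phylum)]
        sub = _caterpillar(species)
        subtrees.append(sub)
    if len(subtrees) == 1:
        root = subtrees[0]
    else:
        root = _balanced_tree(config.phylum_names)
        # replace phylum tips by their species subtrees
        for tip in list(root.tips()):
            idx = config.phylum_names.index(tip.name)
            sub = subtrees[idx]
            sub.length = tip.length
            parent = tip.parent
            parent.remove(tip)
            parent.append(sub)
    root.length = None
    return root


def _neutral_version(motif: str) -> str:
    """A same-length string differing from *motif* at every position."""
    return "".join(
        AMINO_ACIDS[(AMINO_ACIDS.index(c) + 1) % len(AMINO_ACIDS)] for c in motif
    )


def _allocate_context_sites(config: SimulationConfig):
    """Deterministically place context-string slots inside conserved blocks,
    round-robin across blocks, avoiding motif intervals."""
    # 2-column margin: an invariant copy flanking a motif could otherwise
    # extend the motif's pattern into a reserved string the scrub cannot fix
    motif_spans: dict[str, list[tuple[int, int]]] = {}
    for m in config.motifs:
        motif_spans.setdefault(m.gene, []).append(
            (m.position - 2, m.position + len(m.motif) + 1)
        )
    segments: list[list] = []  # [gene, cursor, end]
    for gene, start, end, _ in config.conserved_blocks:
        cuts = sorted(
            s for s in motif_spans.get(gene, []) if s[0] <= end and s[1] >= start
        )
        cur = start
        for lo, hi in cuts:
            if cur < lo:
                segments.append([gene, cur, lo - 1])
            cur = hi + 1
        if cur <= end:
            segments.append([gene, cur, end])
    slots: list[tuple[str, int]] = []  # (gene, 1-based start of 5-col slot)
    n_needed = len(config.motifs) * config.context_copies
    width = 6  # 5 residues + 1 spacer
    si = 0
    guard = 0
    while len(slots) < n_needed:
        if not segments:
            raise ValueError(
                "not enough conserved-block space for context strings"
            )
        seg = segments[si % len(segments)]
        if seg[2] - seg[1] + 1 >= width:
            slots.append((seg[0], seg[1]))
            seg[1] += width
            si += 1
        else:
            segments.pop(si % len(segments))
        guard += 1
        if guard > 100000:
            raise ValueError("context slot allocation did not terminate")
    return slots


def simulate(config: SimulationConfig) -> tuple[list[Proteome], SimulationTruth]:
    """Generate proteomes and ground truth; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.genes)
    gene_names = [g for g, _ in config.genes]

    # per-gene rate multipliers (1 outside blocks) and invariant-site masks
    mult: dict[str, np.ndarray] = {
        g: np.ones(L) for g, L in config.genes
    }
    for gene, start, end, m in config.conserved_blocks:
        mult[gene][start - 1 : end] = m
    invariant: dict[str, np.ndarray] = {
        g: np.zeros(L, dtype=bool) for g, L in config.genes
    }

    # root proteome
    root_seq = {g: rng.integers(0, 20, size=L, dtype=np.int64)
                for g, L in config.genes}

    # context strings: motif core with neutral flanks, identical in all
    # species, invariant thereafter
    slots = _allocate_context_sites(config)
    context_sites: list[tuple[str, int, int]] = []
    flank_pool = AMINO_ACIDS
    for mi, m in enumerate(config.motifs):
        core = m.motif[1:-1]
        fl = [c for c in flank_pool if c != m.motif[0]]
        ll = [c for c in flank_pool if c != m.motif[-1]]
        for ci in range(config.context_copies):
            gene, start = slots[mi * config.context_copies + ci]
            copy = fl[ci % len(fl)] + core + ll[(ci + 7) % len(ll)]
            idx = np.array([AMINO_ACIDS.index(c) for c in copy])
            root_seq[gene][start - 1 : start - 1 + len(copy)] = idx
            invariant[gene][start - 1 : start - 1 + len(copy)] = True
            context_sites.append((gene, start, start + len(copy) - 1))

    # motif sites: neutral (anti-motif) content at the root, invariant
    for m in config.motifs:
        neutral = _neutral_version(m.motif)
        idx = np.array([AMINO_ACIDS.index(c) for c in neutral])
        sl = slice(m.position - 1, m.position - 1 + len(m.motif))
        root_seq[m.gene][sl] = idx
        invariant[m.gene][sl] = True

    # Reserved patterns: each motif's full string and its two (K-1)-mers.
    # Chance occurrences outside the engineered sites would distort the
    # controlled prefix/suffix counts that set the motif's CV score, so the
    # generator destroys them wherever they arise.
    reserved: list[np.ndarray] = []
    for m in config.motifs:
        for pat in {m.motif, m.motif[:-1], m.motif[1:]}:
            reserved.append(np.array([AMINO_ACIDS.index(c) for c in pat]))

    def scrub(seq: dict[str, np.ndarray]) -> None:
        for g, _L in config.genes:
            arr = seq[g]
            inv = invariant[g]
            for _round in range(100):
                dirty = False
                s = _AA[arr].tobytes()
                for pat in reserved:
                    pb = _AA[pat].tobytes()
                    start = s.find(pb)
                    while start != -1:
                        span = range(start, start + len(pat))
                        free = [j for j in span if not inv[j]]
                        if free:
                            arr[free[0]] = (arr[free[0]] + 7) % 20
                            dirty = True
                        start = s.find(pb, start + 1)
                if not dirty:
                    break
                s = _AA[arr].tobytes()
            else:
                raise RuntimeError("reserved-pattern scrub did not converge")

    scrub(root_seq)

    tree = build_true_tree(config)
    phylum_of: dict[str, str] = {}
    for ph in config.phylum_names:
        for i in range(config.species_per_phylum):
            phylum_of[f"{ph}_s{i + 1}"] = ph

    # map each motif to its clade's MRCA: the shallowest node whose tip
    # phylum set equals the clade
    def node_phyla(node: TreeNode) -> frozenset[str]:
        return frozenset(phylum_of[t.name] for t in node.tips()) if not node.is_tip() \
            else frozenset({phylum_of[node.name]})

    motifs_at: dict[int, list[Motif]] = {}
    for m in config.motifs:
        target = frozenset(m.clade)
        best = None
        for node in tree.preorder():
            if node_phyla(node) == target:
                best = node
                break  # preorder: shallowest first
        if best is None:
            raise ValueError(f"no tree node matches motif clade {m.clade}")
        motifs_at.setdefault(id(best), []).append(m)

    genomes: dict[str, dict[str, np.ndarray]] = {}

    def evolve(node: TreeNode, parent_seq: dict[str, np.ndarray]) -> None:
        seq = {g: s.copy() for g, s in parent_seq.items()}
        if node.length:
            p_branch = config.substitution_rate * node.length
            for g, L in config.genes:
                site_p = p_branch * mult[g]
                site_p[invariant[g]] = 0.0
                mask = rng.random(L) < site_p
                n_mut = int(mask.sum())
                if n_mut:
                    # uniform replacement over the other 19 residues
                    shift = rng.integers(1, 20, size=n_mut)
                    seq[g][mask] = (seq[g][mask] + shift) % 20
            scrub(seq)
        for m in motifs_at.get(id(node), ()):
            idx = np.array([AMINO_ACIDS.index(c) for c in m.motif])
            seq[m.gene][m.position - 1 : m.position - 1 + len(m.motif)] = idx
        if node.is_tip():
            genomes[node.name] = seq
        else:
            for child in node.children:
                evolve(child, seq)

    evolve(tree, root_seq)

    proteomes = []
    for ph in config.phylum_names:
        for i in range(config.species_per_phylum):
            sid = f"{ph}_s{i + 1}"
            proteins = [
                ProteinRecord(g, _AA[genomes[sid][g]].tobytes().decode())
                for g in gene_names
            ]
            proteomes.append(
                Proteome(species_id=sid, proteins=proteins, phylum=ph)
            )

    motif_species = {
        m.motif: [s for s, ph in phylum_of.items() if ph in set(m.clade)]
        for m in config.motifs
    }
    truth = SimulationTruth(
        tree=tree,
        phylum_of=phylum_of,
        motifs=list(config.motifs),
        motif_species=motif_species,
        blocks=config.conserved_blocks,
        genes=config.genes,
        context_sites=context_sites,
    )
    return proteomes, truth


def concatenated_alignment(proteomes: list[Proteome]) -> Alignment:
    """Gene-wise concatenation of simulated (indel-free) proteomes as an
    alignment; genes in each proteome's stored order."""
    rows = ["".join(rec.sequence for rec in p.proteins) for p in proteomes]
    return Alignment.from_rows([p.species_id for p in proteomes], rows)


def species_table_for(proteomes: list[Proteome]) -> SpeciesTable:
    return SpeciesTable(
        [(p.species_id, p.phylum, p.class_label) for p in proteomes]
    )


def markov_null_sequences(
    n_sequences: int,
    length: int,
    alpha: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Sequences from stationary first-order Markov chains over the 20
    amino acids (one independently drawn transition matrix per sequence,
    rows ~ Dirichlet(alpha)).  This is the null model for checking the
    chi-square test's size: an order-(K-2) Markov chain for K=3.

    Generation is vectorized across sequences.
    """
    rng = np.random.default_rng(seed)
    A = len(AMINO_ACIDS)
    P = rng.dirichlet(np.full(A, alpha), size=(n_sequences, A))
    cum = np.cumsum(P, axis=2)
    states = rng.integers(0, A, size=n_sequences)
    seqs = np.empty((n_sequences, length), dtype=np.int8)
    seqs[:, 0] = states
    u = rng.random((length, n_sequences))
    rows_idx = np.arange(n_sequences)
    for t in range(1, length):
        c = cum[rows_idx, states]
        states = (u[t][:, None] < c).argmax(axis=1)
        seqs[:, t] = states
    return [_AA[row].tobytes().decode() for row in seqs]


# ---------------------------------------------------------------------------
# named, seed-pinned fixtures


def _small4x5_config() -> SimulationConfig:
    blocks = (
        ("cox1", 101, 190, 0.1),
        ("cox3", 41, 120, 0.1),
        ("nad1", 41, 120, 0.1),
        ("nad4", 141, 220, 0.1),
        ("nad5", 201, 290, 0.1),
        ("cob", 101, 180, 0.1),
    )
    motifs = (
        Motif(("P1",), "cox1", 120, "WHWHW"),
        Motif(("P2",), "cox3", 60, "YCYCY"),
        Motif(("P3",), "nad5", 220, "HQHQH"),
        Motif(("P4",), "cob", 120, "WCWCW"),
        Motif(("P1", "P2"), "nad4", 170, "QWQWY"),
        Motif(("P3", "P4"), "nad1", 70, "CHCHY"),
    )
    return SimulationConfig(
        n_phyla=4,
        species_per_phylum=5,
        substitution_rate=0.05,
        conserved_blocks=blocks,
        motifs=motifs,
        context_copies=10,
        seed=4501,
    )


def _twoclade_config() -> SimulationConfig:
    genes = (("g1", 150), ("g2", 200), ("g3", 120))
    blocks = (("g1", 31, 90, 0.1), ("g2", 41, 130, 0.1), ("g3", 31, 90, 0.1))
    motifs = (
        Motif(("P1",), "g1", 50, "WHWHW"),
        Motif(("P2",), "g2", 60, "YCYCY"),
    )
    return SimulationConfig(
        n_phyla=2,
        species_per_phylum=4,
        genes=genes,
        substitution_rate=0.05,
        conserved_blocks=blocks,
        motifs=motifs,
        context_copies=10,
        seed=101,
    )


def _vertlike_config() -> SimulationConfig:
    blocks = (
        ("cox1", 101, 190, 0.1),
        ("cox3", 41, 120, 0.1),
        ("nad1", 41, 120, 0.1),
        ("nad4", 141, 220, 0.1),
        ("nad5", 201, 290, 0.1),
    )
    motifs = (
        Motif(("P1",), "cox1", 120, "WHWHW"),
        Motif(("P2",), "cox3", 60, "YCYCY"),
        Motif(("P3",), "nad5", 220, "HQHQH"),
        Motif(("P4",), "nad4", 170, "QWQWY"),
        Motif(("P5",), "nad1", 70, "CHCHY"),
    )
    return SimulationConfig(
        n_phyla=5,
        species_per_phylum=2,
        substitution_rate=0.05,
        conserved_blocks=blocks,
        motifs=motifs,
        context_copies=10,
        seed=1002,
    )


FIXTURES = {
    "small4x5": _small4x5_config,
    "twoclade-minimal": _twoclade_config,
    "vertebrate-like10x2": _vertlike_config,
}


def fixture(name: str) -> tuple[list[Proteome], SimulationTruth]:
    """A named, seed-pinned simulated dataset used throughout the tests."""
    try:
        config = FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return simulate(config)
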