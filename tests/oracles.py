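"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own counting/scoring code paths:
counts come from explicit substring enumeration, scores and variances from
dense dictionaries evaluated literally from the definitions.
"""

from __future__ import annotations

import math
from collections import Counter


def naive_counts(sequences: list[str], K: int) -> tuple[dict[str, int], int]:
    """Enumerate every length-K substring of every sequence separately."""
    counts: Counter[str] = Counter()
    total = 0
    for seq in sequences:
        for i in range(len(seq)):
            sub = seq[i : i + K]
            if len(sub) == K:
                counts[sub] += 1
                total += 1
    return dict(counts), total


def naive_markov_expected(sequences: list[str], K: int, s: str) -> float:
    cK1, t1 = naive_counts(sequences, K - 1)
    cK2, t2 = naive_counts(sequences, K - 2)
    core = s[1:-1]
    if cK2.get(core, 0) == 0:
        return 0.0
    return (cK1.get(s[:-1], 0) / t1) * (cK1.get(s[1:], 0) / t1) / (
        cK2.get(core, 0) / t2
    )


def naive_cv(sequences: list[str], K: int) -> dict[str, float]:
    """Dense evaluation of (p - p0)/p0 over every string with p or p0 > 0."""
    cK, tK = naive_counts(sequences, K)
    cK1, t1 = naive_counts(sequences, K - 1)
    cK2, t2 = naive_counts(sequences, K - 2)
    support = set(cK)
    for w1 in cK1:
        for w2 in cK1:
            if w1[1:] == w2[:-1]:
                support.add(w1 + w2[-1])
    out: dict[str, float] = {}
    for s in support:
        p = cK.get(s, 0) / tK
        core = s[1:-1]
        if cK2.get(core, 0):
            p0 = (cK1.get(s[:-1], 0) / t1) * (cK1.get(s[1:], 0) / t1) / (
                cK2[core] / t2
            )
        else:
            p0 = 0.0
        out[s] = (p - p0) / p0 if p0 > 0 else 0.0
    return out


def naive_variances(rows: list[dict[str, float]]) -> dict[str, float]:
    """Population variance per string over dense-ified rows."""
    support = sorted(set().union(*[set(r) for r in rows]))
    n = len(rows)
    out = {}
    for s in support:
        vals = [r.get(s, 0.0) for r in rows]
        mean = sum(vals) / n
        out[s] = sum((v - mean) ** 2 for v in vals) / n
    return out


def naive_cosine_distance(a: dict[str, float], b: dict[str, float]) -> float:
    support = set(a) | set(b)
    dot = sum(a.get(s, 0.0) * b.get(s, 0.0) for s in support)
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.5
    return (1.0 - dot / (na * nb)) / 2.0


def naive_coverage(sequence: str, keys: set[str]) -> list[int]:
    """All-positions scan: how many key occurrences overlap each position."""
    cov = [0] * len(sequence)
    for key in keys:
        for i in range(len(sequence) - len(key) + 1):
            if sequence[i : i + len(key)] == key:
                for j in range(i, i + len(key)):
                    cov[j] += 1
    return cov


def naive_bipartitions(tree) -> set[frozenset[frozenset[str]]]:
    """Bipartitions via explicit graph cutting (networkx), independent of
    the package's tips()-based extraction."""
    import networkx as nx

    g = nx.Graph()
    ids = {}

    def walk(node):
        ids[id(node)] = len(ids)
        for child in node.children:
            walk(child)
            g.add_edge(ids[id(node)], ids[id(child)])

    walk(tree)
    leaves = {ids[id(t)]: t.name for t in tree.tips()}
    n = len(leaves)
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(name for nid, name in leaves.items() if nid in comp)
        other = frozenset(leaves.values()) - side
        if 1 < len(side) < n - 1:
            splits.add(frozenset({side, other}))
        g.add_edge(u, v)
    return splits
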