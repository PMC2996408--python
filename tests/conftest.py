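"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from bidbg.build import BiGraph, CanonicalEdge, Head
from bidbg.codec import (
    EncodedSeq,
    KMolecule,
    canonical_form,
    reverse_complement,
    reverse_complement_str,
)

FLIP = {"<": ">", ">": "<"}

# Worked-example read sets.  FIG2_READS_PAPER is the printed list; in it
# "GTTC" is not a substring of the source sequence ATGGACCAT or its reverse
# complement, so FIG2_READS uses the source-consistent window "GGTC", under
# which the graph reconstructs TGGACCAT.
FIG2_READS = ["ATGG", "CCAT", "GGAC", "GGTC", "TGGA", "TGGT"]
FIG2_READS_PAPER = ["ATGG", "CCAT", "GGAC", "GTTC", "TGGA", "TGGT"]
FIG2_SOURCE = "ATGGACCAT"
SPURIOUS_READ = "AATGCATC"


def brute_force_graph(seqs, k, include_rc=True):
    """Hash-map construction of the canonical edge multiset, string-based.

    Independent of the sorting pipeline: inserts every (k+1)-window of the
    reads (plus reverse complements) and canonicalises naively with string
    comparisons.  Returns (sorted vertex labels, {edge row: multiplicity}).
    """
    seqs = [s.upper() for s in seqs]
    if include_rc:
        seqs = seqs + [reverse_complement_str(s) for s in seqs if set(s) <= set("ACGT")]
    edges: dict[tuple, int] = {}
    for s in seqs:
        for i in range(len(s) - k):
            z = s[i : i + k + 1]
            if not set(z) <= set("ACGT"):
                continue
            x, y = z[:k], z[1:]
            rx, ry = reverse_complement_str(x), reverse_complement_str(y)
            xh, h1 = (x, ">") if x <= rx else (rx, "<")
            yh, h2 = (y, ">") if y <= ry else (ry, "<")
            if xh <= yh:
                row = (xh, yh, h1, h2)
            else:
                row = (yh, xh, FLIP[h2], FLIP[h1])
            if row[0] == row[1] and row[2] == "<" and row[3] == "<":
                row = (row[0], row[1], ">", ">")
            edges[row] = edges.get(row, 0) + 1
    verts = sorted({r[0] for r in edges} | {r[1] for r in edges})
    return verts, edges


def graph_rows(g: BiGraph) -> dict[tuple, int]:
    """Edge rows of a built graph in the oracle's representation."""
    return {
        (g.label(e.u), g.label(e.v), e.h1.symbol, e.h2.symbol): e.multiplicity
        for e in g.edges
    }


def assert_matches_oracle(g: BiGraph, seqs, k):
    verts, edges = brute_force_graph(seqs, k)
    assert [g.label(i) for i in range(g.n_vertices)] == verts
    assert graph_rows(g) == edges


def random_read_set(rng: random.Random, max_reads=50, min_len=20, max_len=60):
    n = rng.randint(1, max_reads)
    return [
        "".join(rng.choice("ACGT") for _ in range(rng.randint(min_len, max_len)))
        for _ in range(n)
    ]


def random_bigraph(rng: random.Random, max_nodes=10, max_edges=20) -> BiGraph:
    """Random bi-directed graph with arbitrary head orientations.

    Labels are distinct canonical 5-mers; reachability tests ignore them.
    """
    n = rng.randint(2, max_nodes)
    seen: set[int] = set()
    mols: list[KMolecule] = []
    while len(mols) < n:
        code = rng.randrange(4 ** 5)
        canon, _ = canonical_form(EncodedSeq(5, code))
        if canon.code in seen:
            continue
        seen.add(canon.code)
        mols.append(KMolecule(canon, reverse_complement(canon), len(mols)))
    m = rng.randint(1, max_edges)
    keys = set()
    for _ in range(m):
        u, v = sorted((rng.randrange(n), rng.randrange(n)))
        h1, h2 = rng.randrange(2), rng.randrange(2)
        if u == v and h1 and h2:
            h1 = h2 = 0
        keys.add((u, v, h1, h2))
    edges = [CanonicalEdge(u, v, Head(h1), Head(h2), 1) for u, v, h1, h2 in sorted(keys)]
    return BiGraph(k=5, vertices=mols, edges=edges)


@pytest.fixture
def fig2_graph():
    from bidbg.build import build_graph
    from bidbg.seqio import ReadSet

    return build_graph(ReadSet.from_sequences(FIG2_READS), 3)


@pytest.fixture
def spurious_graph():
    from bidbg.build import build_graph
    from bidbg.seqio import ReadSet

    return build_graph(ReadSet.from_sequences([SPURIOUS_READ]), 3)
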