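"""Bi-directed walk semantics: reachability and read spelling.

A walk in a bi-directed graph is valid when, at every intermediate vertex,
the arrowhead on the incoming edge matches the arrowhead on the outgoing
edge (o2 = o1').  Traversing an edge (u,v,h1,h2) from v's side reads the
flip-swapped record (v,u,h2',h1').  The reachability search here works
directly on the edge list with these two rules and never builds the
list-ranking transform, so it can serve as the independent side of the
transform-equivalence (doubled-graph) checks.

Sign convention at the endpoints: leaving or entering "on +" means the
canonical strand takes part, which is head FWD; "−" is head REV.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable

from .build import BiGraph, Head
from .compact import PLUS, list_ranking_transform, smol, snode, ssign


def _traversals(g: BiGraph):
    """All directed readings of the edge list: (from_vertex, near_head,
    to_vertex, far_head)."""
    out = []
    for e in g.edges:
        out.append((e.u, e.h1, e.v, e.h2))
        # flip-swap: the same edge read from the other endpoint
        out.append((e.v, e.h2.flip(), e.u, e.h1.flip()))
    return out


def bidirected_reachable(
    g: BiGraph, frm: tuple[int, int], to: tuple[int, int]
) -> bool:
    """True iff a valid bi-directed walk leaves ``frm``'s vertex on its
    sign's strand and enters ``to``'s vertex on its sign's strand.

    ``frm``/``to`` are (vertex id, sign) with sign 0 = '+' (canonical).
    Walks may revisit vertices; the search is a BFS over (vertex, strand)
    states, which are finite.  The empty walk makes any state reach itself.
    """
    if frm == to:
        return True
    start_head = Head.FWD if frm[1] == PLUS else Head.REV
    goal_head = Head.FWD if to[1] == PLUS else Head.REV
    adj: dict[tuple[int, Head], list[tuple[int, Head]]] = {}
    for u, near, v, far in _traversals(g):
        adj.setdefault((u, near), []).append((v, far))
    start = (frm[0], start_head)
    goal = (to[0], goal_head)
    seen = {start}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        for nxt in adj.get(state, ()):
            if nxt == goal:
                return True
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return False


def _kmer_index(g: BiGraph, k: int) -> dict[str, list[tuple[int, int, int]]]:
    """Map each k-mer to its occurrences (vertex, sign, offset) across both
    strands of every vertex label."""
    index: dict[str, list[tuple[int, int, int]]] = {}
    for vid, mol in enumerate(g.vertices):
        for sign, label in ((0, mol.canonical_str), (1, mol.noncanonical_str)):
            for off in range(len(label) - k + 1):
                index.setdefault(label[off : off + k], []).append((vid, sign, off))
    return index


def read_is_spelled(g: BiGraph, read: str) -> bool:
    """True iff the read maps to a valid bi-directed walk whose spelled
    string equals the read.

    Works on both raw k-mer graphs and compacted graphs: consecutive read
    k-mers must either advance one position inside a vertex label (on one
    strand) or cross an edge from the end of one label to the start of the
    next, with head orientations chaining per the walk rule.
    """
    k = g.k
    if len(read) < k:
        raise ValueError(f"read shorter than k={k} cannot be mapped")
    read = read.upper()
    kmers = [read[i : i + k] for i in range(len(read) - k + 1)]
    index = _kmer_index(g, k)
    label_len = [len(m.canonical_str) for m in g.vertices]

    arc_out: dict[int, list[int]] = {}
    for a, b in list_ranking_transform(g).arcs:
        arc_out.setdefault(a, []).append(b)
    states = set(index.get(kmers[0], ()))
    for nxt_kmer in kmers[1:]:
        targets = index.get(nxt_kmer, ())
        if not targets or not states:
            return False
        target_starts = {(v, s) for v, s, off in targets if off == 0}
        target_set = set(targets)
        new_states = set()
        for vid, sign, off in states:
            inside = (vid, sign, off + 1)
            if inside in target_set:
                new_states.add(inside)
            if off == label_len[vid] - k:  # at label end: may cross an edge
                for b in arc_out.get(snode(vid, sign), ()):
                    if (smol(b), ssign(b)) in target_starts:
                        new_states.add((smol(b), ssign(b), 0))
        states = new_states
    return bool(states)
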