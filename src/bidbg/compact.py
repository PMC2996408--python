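"""Bi-directed chain compaction via a list-ranking transform.

Pointer jumping applied directly to a bi-directed graph can walk into
orientation cycles, so compaction first *doubles* the graph: every molecule
v yields two signed nodes v⁺ (reading the canonical strand) and v⁻ (reading
the reverse complement), and every bi-directed edge (u,v,h1,h2) yields the
directed arc u^{s(h1)} → v^{s(h2)} together with its complement
v^{s(h2)'} → u^{s(h1)'}, where s(FWD)=+, s(REV)=− and ' flips the sign.
Bi-directed reachability in the original graph equals directed reachability
in this doubled graph, so maximal non-branching chains can be ranked with
ordinary list ranking — in memory by pointer jumping, or out of core by
sort-merge pointer doubling with a join-count cycle detector.

Each maximal chain comes with a complementary mirror chain (the reversed
complement node sequence, spelling the reverse-complement label); the pair
is replaced by one new molecule named min{endpoint molecule names} whose
canonical label is the smaller of the two spelled strands.
"""

from __future__ import annotations

import logging
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .build import BiGraph, CanonicalEdge, Head, build_adjacency
from .codec import EncodedSeq, KMolecule, encode, reverse_complement, reverse_complement_str
from .sorting import RecordFile, SortConfig, external_sort

logger = logging.getLogger("bidbg")

PLUS, MINUS = 0, 1


def snode(mol: int, sign: int) -> int:
    """Signed-node id: molecule id with the sign in the low bit."""
    return (mol << 1) | sign


def smol(s: int) -> int:
    return s >> 1


def ssign(s: int) -> int:
    return s & 1


def scomp(s: int) -> int:
    """Complement signed node: same molecule, other strand."""
    return s ^ 1


def sname(s: int, g: BiGraph) -> str:
    return f"{g.names[smol(s)]}{'+' if ssign(s) == PLUS else '-'}"


@dataclass
class DoubledGraph:
    """Directed graph on signed nodes produced by the list-ranking transform.

    ``arc_edge`` maps each arc back to the index of the bi-directed edge it
    came from (used to carry multiplicities through compaction).
    """

    nodes: set[int]
    arcs: set[tuple[int, int]]
    arc_edge: dict[tuple[int, int], int] = field(default_factory=dict)

    def degrees(self) -> tuple[dict[int, int], dict[int, int]]:
        d_in: dict[int, int] = {}
        d_out: dict[int, int] = {}
        for a, b in self.arcs:
            d_out[a] = d_out.get(a, 0) + 1
            d_in[b] = d_in.get(b, 0) + 1
        return d_in, d_out


def head_sign(h: Head) -> int:
    return PLUS if h is Head.FWD else MINUS


def sign_head(s: int) -> Head:
    return Head.FWD if s == PLUS else Head.REV


def list_ranking_transform(g: BiGraph) -> DoubledGraph:
    """Replace every bi-directed edge with its complementary arc pair.

    A self-loop with heads (FWD,REV) or (REV,FWD) yields an arc equal to its
    own complement, which is stored once.
    """
    nodes = {snode(v, s) for v in range(g.n_vertices) for s in (PLUS, MINUS)}
    arcs: set[tuple[int, int]] = set()
    arc_edge: dict[tuple[int, int], int] = {}
    for i, e in enumerate(g.edges):
        a = snode(e.u, head_sign(e.h1))
        b = snode(e.v, head_sign(e.h2))
        for arc in ((a, b), (scomp(b), scomp(a))):
            if arc not in arcs:
                arcs.add(arc)
                arc_edge[arc] = i
    return DoubledGraph(nodes, arcs, arc_edge)


@dataclass
class PruneResult:
    pruned: DoubledGraph
    vp: set[int]            # branching signed nodes (closed under complement)
    ep: set[tuple[int, int]]  # arcs incident to vp


def prune_branches(dg: DoubledGraph) -> PruneResult:
    """Remove branching signed nodes and their incident arcs; what remains
    is a disjoint union of simple directed paths and cycles."""
    d_in, d_out = dg.degrees()
    vp = {s for s in dg.nodes if d_in.get(s, 0) > 1 or d_out.get(s, 0) > 1}
    ep = {arc for arc in dg.arcs if arc[0] in vp or arc[1] in vp}
    keep = dg.arcs - ep
    pruned = DoubledGraph(
        dg.nodes - vp, keep, {a: dg.arc_edge[a] for a in keep}
    )
    return PruneResult(pruned, vp, ep)


@dataclass
class CycleReport:
    """List-ranking outcome diagnostics.

    ``join_counts`` is J(S) per sort-merge phase; a cycle is declared when
    J(S) repeats across two consecutive phases.  ``sizes`` is |S| per phase.
    ``broken_arcs`` records the arc dropped from each reported cycle so the
    compacted output is an open chain.
    """

    cycles: list[list[int]] = field(default_factory=list)
    join_counts: list[int] = field(default_factory=list)
    sizes: list[int] = field(default_factory=list)
    phases: int = 0
    rounds: int = 0
    broken_arcs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def has_cycles(self) -> bool:
        return bool(self.cycles)


def _succ_map(pruned: DoubledGraph) -> dict[int, int]:
    succ: dict[int, int] = {}
    for a, b in pruned.arcs:
        if a in succ:
            raise AssertionError("pruned graph has a node with out-degree > 1")
        succ[a] = b
    return succ


def _order_cycles(members: set[int], succ: dict[int, int]) -> list[list[int]]:
    """Group cycle members into ordered cycles, each starting at its minimum
    signed node."""
    cycles = []
    seen: set[int] = set()
    for s in sorted(members):
        if s in seen:
            continue
        cyc = [s]
        seen.add(s)
        t = succ[s]
        while t != s:
            cyc.append(t)
            seen.add(t)
            t = succ[t]
        cycles.append(cyc)
    return cycles


def _chains_from_ranks(
    resolved: dict[int, tuple[int, int]], tails: Iterable[int]
) -> list[list[int]]:
    """Assemble ordered chains from (tail, distance-to-tail) ranks."""
    groups: dict[int, list[tuple[int, int]]] = {}
    for t in tails:
        groups.setdefault(t, []).append((0, t))
    for s, (t, d) in resolved.items():
        groups.setdefault(t, []).append((d, s))
    chains = []
    for t in sorted(groups):
        members = sorted(groups[t], reverse=True)  # head = max distance
        chains.append([s for _, s in members])
    return chains


def _find_cycle_nodes(succ: dict[int, int], nodes: Iterable[int]) -> set[int]:
    """Nodes lying on directed cycles of a functional (out-degree <= 1) graph."""
    color: dict[int, int] = {}  # 1 = on current walk, 2 = finished
    cyc: set[int] = set()
    for s in nodes:
        if color.get(s):
            continue
        path: list[int] = []
        cur: Optional[int] = s
        while cur is not None and color.get(cur) is None:
            color[cur] = 1
            path.append(cur)
            cur = succ.get(cur)
        if cur is not None and color.get(cur) == 1:
            cyc.update(path[path.index(cur):])
        for p in path:
            color[p] = 2
    return cyc


def rank_chains_memory(
    pruned: DoubledGraph,
) -> tuple[list[list[int]], CycleReport]:
    """Rank every maximal path of the pruned graph by pointer jumping.

    Each round replaces every node's pointer with its pointer's pointer and
    accumulates distances, so the longest chain C resolves in
    ceil(log2 C) + 1 rounds.  Cycle components (no head to rank from) are
    identified first and reported; isolated nodes become length-1 chains.
    """
    succ = _succ_map(pruned)
    cycle_nodes = _find_cycle_nodes(succ, pruned.nodes)
    nodes = [s for s in pruned.nodes if s not in cycle_nodes]
    ptr = {}
    dist = {}
    for s in nodes:
        if s in succ:
            ptr[s] = succ[s]
            dist[s] = 1
        else:
            ptr[s] = s
            dist[s] = 0
    report = CycleReport()
    report.cycles = _order_cycles(cycle_nodes, succ)
    max_rounds = max(1, math.ceil(math.log2(max(2, len(nodes) or 2)))) + 2
    for _ in range(max_rounds):
        moved = False
        new_ptr = dict(ptr)
        new_dist = dict(dist)
        for s in nodes:
            t = ptr[s]
            if ptr[t] != t:
                new_dist[s] = dist[s] + dist[t]
                new_ptr[s] = ptr[t]
                moved = True
        ptr, dist = new_ptr, new_dist
        report.rounds += 1
        if not moved:
            break
    resolved = {s: (ptr[s], dist[s]) for s in nodes if ptr[s] != s}
    tails = [s for s in nodes if ptr[s] == s]
    chains = _chains_from_ranks(resolved, tails)
    return chains, report


# ---------------------------------------------------------------------------
# Out-of-core list ranking: sort-merge pointer doubling with join counts.
# ---------------------------------------------------------------------------

_TUPLE_WIDTH = 12  # three big-endian u32 fields


def write_rank_tuples(succ: dict[int, int], path: Path) -> RecordFile:
    """Serialise the successor relation as fixed-width (x, y, dist) tuples."""
    with open(path, "wb") as fh:
        for x in sorted(succ):
            fh.write(x.to_bytes(4, "big") + succ[x].to_bytes(4, "big") + (1).to_bytes(4, "big"))
    return RecordFile.from_path(path, _TUPLE_WIDTH)


def _iter_tuples(blob: bytes):
    for i in range(0, len(blob), _TUPLE_WIDTH):
        yield (
            int.from_bytes(blob[i : i + 4], "big"),
            int.from_bytes(blob[i + 4 : i + 8], "big"),
            int.from_bytes(blob[i + 8 : i + 12], "big"),
        )


def _external_sorted_tuples(
    records: list[tuple[int, int, int]], key_first: int, cfg: SortConfig, work: Path, tag: str
) -> list[tuple[int, int, int]]:
    """Sort (x,y,d) tuples by one field through the external sorting engine.

    ``key_first`` selects the leading field (0 sorts by x, 1 by y); the
    record is packed key-major so full-record byte order sorts by the key.
    """
    path = work / f"{tag}.bin"
    with open(path, "wb") as fh:
        for x, y, d in records:
            key = (x, y) if key_first == 0 else (y, x)
            fh.write(key[0].to_bytes(4, "big") + key[1].to_bytes(4, "big") + d.to_bytes(4, "big"))
    sorted_file = external_sort(RecordFile.from_path(path, _TUPLE_WIDTH), cfg,
                                out_path=work / f"{tag}.sorted")
    out = []
    for a, b, d in _iter_tuples(sorted_file.read_all()):
        out.append((a, b, d) if key_first == 0 else (b, a, d))
    sorted_file.path.unlink(missing_ok=True)
    path.unlink(missing_ok=True)
    return out


def rank_chains_external(
    tuples: RecordFile,
    cfg: Optional[SortConfig] = None,
    keep_files: bool = False,
) -> tuple[list[list[int]], CycleReport]:
    """Out-of-core list ranking by repeated sort-merge pointer doubling.

    Each phase sorts the active tuple set S by target and a copy S' by
    source, scan-merges them, and replaces every joinable pair
    (x,y),(y,y') by the doubled tuple (x,y').  The join count
    J(S) = #{(x,y) ∈ S : ∃(y,z) ∈ S} is recorded per phase: on acyclic
    inputs it strictly decreases to zero; if it repeats across two
    consecutive phases the remaining tuples lie on cycles, which are
    reported.  Tuples whose target has left S resolve against the
    accumulated (tail, distance) table.
    """
    cfg = cfg or SortConfig()
    report = CycleReport()
    tmp_root = Path(cfg.tmp_dir) if cfg.tmp_dir else Path(tempfile.gettempdir())
    work = Path(tempfile.mkdtemp(prefix="bidbg-rank-", dir=tmp_root))

    active = list(_iter_tuples(tuples.path.read_bytes()))
    succ0 = {x: y for x, y, _ in active}
    sources = set(succ0)
    tails = {y for _, y, _ in active} - sources
    resolved: dict[int, tuple[int, int]] = {}
    prev_j: Optional[int] = None
    try:
        while active:
            report.sizes.append(len(active))
            by_y = _external_sorted_tuples(active, 1, cfg, work, f"S-{report.phases}")
            by_x = _external_sorted_tuples(active, 0, cfg, work, f"Sp-{report.phases}")
            # linear scan-merge: match S tuples (x,y) with S' tuples (y,z)
            nxt: list[tuple[int, int, int]] = []
            unjoined: list[tuple[int, int, int]] = []
            j_count = 0
            i = 0
            for x, y, d in by_y:
                while i < len(by_x) and by_x[i][0] < y:
                    i += 1
                if i < len(by_x) and by_x[i][0] == y:
                    y2, z, d2 = by_x[i]
                    nxt.append((x, z, d + d2))
                    j_count += 1
                else:
                    unjoined.append((x, y, d))
            report.join_counts.append(j_count)
            report.phases += 1
            for x, y, d in unjoined:
                if y in tails:
                    resolved[x] = (y, d)
                else:
                    t, dt = resolved[y]  # resolved in an earlier phase
                    resolved[x] = (t, d + dt)
            if prev_j is not None and j_count == prev_j and j_count > 0:
                members = {x for x, _, _ in nxt}
                report.cycles = _order_cycles(members, succ0)
                break
            prev_j = j_count
            active = nxt
    finally:
        if not keep_files:
            import shutil

            shutil.rmtree(work, ignore_errors=True)
    cycle_members = {s for cyc in report.cycles for s in cyc}
    resolved = {s: v for s, v in resolved.items() if s not in cycle_members}
    chains = _chains_from_ranks(resolved, tails)
    return chains, report


def spell_chain(nodes: Sequence[int], g: BiGraph, k: Optional[int] = None) -> str:
    """Spell a chain's label: the strand-oriented label of the first node,
    then the non-overlapping tail of each subsequent node's label (adjacent
    labels overlap by k−1)."""
    k = k if k is not None else g.k
    if not nodes:
        return ""
    ov = k - 1

    def oriented(s: int) -> str:
        m = g.vertices[smol(s)]
        return m.canonical_str if ssign(s) == PLUS else m.noncanonical_str

    label = oriented(nodes[0])
    for prev, cur in zip(nodes, nodes[1:]):
        lab = oriented(cur)
        if label[-ov:] != lab[:ov]:
            raise ValueError(
                f"broken adjacency between signed nodes {sname(prev, g)} and "
                f"{sname(cur, g)}: labels do not overlap by {ov}"
            )
        label += lab[ov:]
    return label


def _complement_chain(chain: Sequence[int]) -> tuple[int, ...]:
    return tuple(scomp(s) for s in reversed(chain))


def _break_cycles(
    cycles: list[list[int]], report: CycleReport
) -> list[list[int]]:
    """Turn reported cycles into open chains, keeping complement pairing.

    Each cycle and its mirror are broken at the pair's globally minimum
    signed node so the broken chains remain exact reversed complements of
    one another; the dropped arc is recorded.
    """
    by_set = {frozenset(c): c for c in cycles}
    done: set[frozenset] = set()
    chains: list[list[int]] = []
    for key, cyc in by_set.items():
        if key in done:
            continue
        comp_key = frozenset(scomp(s) for s in cyc)
        done.add(key)
        self_comp = comp_key == key
        if not self_comp:
            done.add(comp_key)
        start = min(min(cyc), min(comp_key))
        if start in key:
            base = cyc
        else:
            base = by_set[comp_key]
        i = base.index(start)
        chain = base[i:] + base[:i]
        report.broken_arcs.append((chain[-1], chain[0]))
        chains.append(chain)
        if self_comp:
            logger.info("self-complementary cycle of %d nodes broken open", len(chain))
        else:
            mirror = list(_complement_chain(chain))
            report.broken_arcs.append((mirror[-1], mirror[0]))
            chains.append(mirror)
    return chains


def compact(
    g: BiGraph,
    cfg: Optional[SortConfig] = None,
    mode: str = "memory",
) -> BiGraph:
    """Compact all maximal non-branching chains of a bi-directed graph.

    Transform → prune → rank (in-memory pointer jumping or out-of-core
    sort-merge) → merge each chain with its complementary mirror into one
    new molecule (label: the smaller strand of the spelled pair; name:
    min of the endpoint molecule names) → re-target the boundary arcs and
    fold them back into bi-directed edges.  Reported cycles are broken open
    at their minimum signed node.  The result of compacting a compacted
    graph is the identity.
    """
    if mode not in ("memory", "external"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or SortConfig()
    dg = list_ranking_transform(g)
    pr = prune_branches(dg)

    if mode == "memory":
        chains, report = rank_chains_memory(pr.pruned)
    else:
        succ = _succ_map(pr.pruned)
        linked = set(succ) | set(succ.values())
        if succ:
            tmp_root = Path(cfg.tmp_dir) if cfg.tmp_dir else Path(tempfile.gettempdir())
            tmp_root.mkdir(parents=True, exist_ok=True)
            with tempfile.NamedTemporaryFile(
                prefix="bidbg-tuples-", dir=tmp_root, delete=False
            ) as fh:
                tpath = Path(fh.name)
            tuples = write_rank_tuples(succ, tpath)
            chains, report = rank_chains_external(tuples, cfg)
            tpath.unlink(missing_ok=True)
        else:
            chains, report = [], CycleReport()
        chains = chains + [[s] for s in sorted(pr.pruned.nodes - linked)]

    chains = chains + _break_cycles(report.cycles, report)

    # --- pair each chain with its complementary mirror -------------------
    by_key = {tuple(c): c for c in chains}
    new_molecules: list[tuple[int, str, bool]] = []  # (name, canonical label, self_comp)
    node_rep: dict[int, tuple[int, int]] = {}  # chain head/tail -> (new index, sign)
    seen: set[tuple] = set()
    for key in sorted(by_key):
        if key in seen:
            continue
        chain = by_key[key]
        mirror = _complement_chain(chain)
        if mirror not in by_key and mirror != key:
            raise AssertionError("chain lacks its complementary mirror")
        seen.add(key)
        seen.add(mirror)
        label = spell_chain(chain, g)
        label_rc = reverse_complement_str(label)
        canon = min(label, label_rc)
        self_comp = label == label_rc
        if self_comp and mirror != key:
            logger.info("self-complementary chain label %s", canon[:40])
        name = min(g.names[smol(chain[0])], g.names[smol(chain[-1])])
        idx = len(new_molecules)
        new_molecules.append((name, canon, self_comp))
        sign_c = PLUS if label == canon else MINUS
        sign_m = MINUS if sign_c == PLUS else PLUS
        if self_comp:
            sign_c, sign_m = PLUS, MINUS
        if mirror == key:
            # self-mirror chain (m+ ... m-): the head takes +, the tail -,
            # which keeps arc symmetry; the label is its own rc so either
            # strand reads the same string.
            node_rep[chain[0]] = (idx, PLUS)
            node_rep[chain[-1]] = (idx, MINUS)
        else:
            node_rep[chain[0]] = (idx, sign_c)
            node_rep[chain[-1]] = (idx, sign_c)
            node_rep[mirror[0]] = (idx, sign_m)
            node_rep[mirror[-1]] = (idx, sign_m)

    # branching molecules survive unchanged
    branch_mols = sorted({smol(s) for s in pr.vp})
    for m in branch_mols:
        idx = len(new_molecules)
        new_molecules.append((g.names[m], g.vertices[m].canonical_str, False))
        node_rep[snode(m, PLUS)] = (idx, PLUS)
        node_rep[snode(m, MINUS)] = (idx, MINUS)

    order = sorted(range(len(new_molecules)), key=lambda i: new_molecules[i][0])
    newpos = {old: new for new, old in enumerate(order)}
    vertices = []
    names = []
    for old in order:
        name, canon, _ = new_molecules[old]
        seq = encode(canon)
        vertices.append(KMolecule(seq, reverse_complement(seq), len(vertices)))
        names.append(name)

    # --- re-target boundary arcs and fold back into bi-directed edges ----
    edge_map: dict[tuple[int, int, int, int], int] = {}
    for a, b in sorted(pr.ep):
        u, su = newpos[node_rep[a][0]], node_rep[a][1]
        v, sv = newpos[node_rep[b][0]], node_rep[b][1]
        h1, h2 = sign_head(su), sign_head(sv)
        if u > v:
            u, v, h1, h2 = v, u, h2.flip(), h1.flip()
        if u == v and h1 is Head.REV and h2 is Head.REV:
            h1 = h2 = Head.FWD
        mult = g.edges[dg.arc_edge[(a, b)]].multiplicity
        kk = (u, v, int(h1), int(h2))
        if kk not in edge_map:
            edge_map[kk] = mult
    edges = [
        CanonicalEdge(u, v, Head(h1), Head(h2), mult)
        for (u, v, h1, h2), mult in sorted(edge_map.items())
    ]

    return BiGraph(
        k=g.k,
        vertices=vertices,
        edges=edges,
        names=names,
        compacted=True,
        cycle_report=report,
    )
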