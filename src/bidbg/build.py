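"""Sorting-based construction of bi-directed de Bruijn graphs from reads.

The pipeline mirrors the four-step construction it implements:

1. every (k+1)-mer window of the reads *and their reverse complements*
   induces one canonical bi-directed edge record — a fixed-width integer
   packing (û, v̂, h1, h2) with û ≤ v̂ after endpoint normalisation;
2. the records are sorted (in-memory LSD radix, or external R-way merge
   under a memory budget) and duplicate runs are collapsed, recording each
   edge's multiplicity;
3. the unique edge endpoints are collected, sorted and given dense ids;
4. an adjacency index is built over the edge list.

Vertices are k-molecules: a canonical k-mer paired with its reverse
complement, one vertex per double-stranded k-mer.  Each edge carries a head
(▷ = FWD, ◁ = REV) at either end naming which strand of the molecule takes
part in the k−1 overlap.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .codec import (
    EncodedSeq,
    KMolecule,
    encode,
    rc_code,
    require_odd_k,
    reverse_complement,
    _BASE_TO_BITS,
)
from .seqio import ReadSet, with_reverse_complements
from .sorting import (
    RecordFile,
    SortConfig,
    SortTelemetry,
    external_sort,
    sort_bytes_blob,
)

logger = logging.getLogger("bidbg")


class Head(IntEnum):
    """Arrowhead orientation at an edge endpoint.

    FWD (▷) means the molecule's canonical strand takes part in the overlap,
    REV (◁) its reverse complement.
    """

    FWD = 0
    REV = 1

    def flip(self) -> "Head":
        return Head(1 - self.value)

    @property
    def symbol(self) -> str:
        return ">" if self is Head.FWD else "<"

    @classmethod
    def from_symbol(cls, s: str) -> "Head":
        if s == ">":
            return cls.FWD
        if s == "<":
            return cls.REV
        raise ValueError(f"malformed head symbol {s!r} (expected '>' or '<')")


@dataclass(frozen=True)
class EdgeKey:
    """A canonical bi-directed edge before multiplicity accounting."""

    u: EncodedSeq
    v: EncodedSeq
    h1: Head
    h2: Head

    def as_strings(self) -> tuple[str, str, str, str]:
        return str(self.u), str(self.v), self.h1.symbol, self.h2.symbol


@dataclass
class CanonicalEdge:
    """Normalised bi-directed edge between dense vertex ids, u <= v."""

    u: int
    v: int
    h1: Head
    h2: Head
    multiplicity: int = 1

    def key(self) -> tuple[int, int, int, int]:
        return (self.u, self.v, int(self.h1), int(self.h2))


def _canonical_edge_codes(z: int, k: int) -> tuple[int, int, int, int]:
    """STEP-1 case analysis on packed codes.

    z is a (k+1)-mer code; x = z[1..k], y = z[2..k+1].  Heads start FWD where
    the k-mer is already canonical; if û > v̂ the record is flip-swapped so
    the smaller canonical k-mer comes first.  The flip-swapped record denotes
    the same bi-directed edge read from the other side.
    """
    mask_k = (1 << (2 * k)) - 1
    rcz = rc_code(z, k + 1)
    x = z >> 2
    y = z & mask_k
    rcx = rcz & mask_k
    rcy = rcz >> 2
    if x <= rcx:
        xh, h1 = x, Head.FWD
    else:
        xh, h1 = rcx, Head.REV
    if y <= rcy:
        yh, h2 = y, Head.FWD
    else:
        yh, h2 = rcy, Head.REV
    if xh <= yh:
        u, v, o1, o2 = xh, yh, h1, h2
    else:
        u, v, o1, o2 = yh, xh, h2.flip(), h1.flip()
    if u == v and o1 is Head.REV and o2 is Head.REV:
        # (u,u,REV,REV) and (u,u,FWD,FWD) are the same edge under the
        # flip-swap equivalence (e.g. z=AAAA vs z=TTTT); normalise.
        o1 = o2 = Head.FWD
    return u, v, int(o1), int(o2)


def canonical_edge(z: EncodedSeq, k: int) -> EdgeKey:
    """Canonical bi-directed edge of one (k+1)-mer."""
    require_odd_k(k)
    if z.length != k + 1:
        raise ValueError(f"expected a {k + 1}-mer, got length {z.length}")
    u, v, h1, h2 = _canonical_edge_codes(z.code, k)
    return EdgeKey(EncodedSeq(k, u), EncodedSeq(k, v), Head(h1), Head(h2))


def record_width(k: int) -> int:
    """Bytes per packed edge record: 2k bits per endpoint plus two head bits."""
    return (4 * k + 2 + 7) // 8


def pack_record(u: int, v: int, h1: int, h2: int, k: int) -> int:
    return (u << (2 * k + 2)) | (v << 2) | (h1 << 1) | h2


def unpack_record(rec: int, k: int) -> tuple[int, int, int, int]:
    mask_k = (1 << (2 * k)) - 1
    return (rec >> (2 * k + 2)) & mask_k, (rec >> 2) & mask_k, (rec >> 1) & 1, rec & 1


def _read_window_records(read: str, k: int) -> Iterator[int]:
    """Packed edge records for every clean (k+1)-window of one read.

    Rolling 2-bit forward and reverse-complement codes keep each window O(1).
    """
    w = k + 1
    mask_w = (1 << (2 * w)) - 1
    top_shift = 2 * (w - 1)
    z = 0
    rcz = 0
    run = 0
    mask_k = (1 << (2 * k)) - 1
    for ch in read.upper():
        b = _BASE_TO_BITS.get(ch)
        if b is None:
            run = 0
            z = 0
            rcz = 0
            continue
        z = ((z << 2) | b) & mask_w
        rcz = ((b ^ 3) << top_shift) | (rcz >> 2)
        run += 1
        if run < w:
            continue
        x = z >> 2
        y = z & mask_k
        rcx = rcz & mask_k
        rcy = rcz >> 2
        if x <= rcx:
            xh, o1 = x, 0
        else:
            xh, o1 = rcx, 1
        if y <= rcy:
            yh, o2 = y, 0
        else:
            yh, o2 = rcy, 1
        if xh <= yh:
            rec = (xh << (2 * k + 2)) | (yh << 2) | (o1 << 1) | o2
            if xh == yh and o1 and o2:
                rec ^= 3  # self-loop (REV,REV) -> (FWD,FWD)
        else:
            rec = (yh << (2 * k + 2)) | (xh << 2) | ((o2 ^ 1) << 1) | (o1 ^ 1)
        yield rec


def emit_edge_records(rs: ReadSet, k: int, sink) -> int:
    """Stream one packed, fixed-width record per valid (k+1)-window into
    ``sink`` (anything with .write accepting bytes).  ``rs`` must already
    contain the reverse complements (R*).  Returns the record count."""
    require_odd_k(k)
    width = record_width(k)
    count = 0
    skipped = 0
    buf = bytearray()
    for read in rs.reads:
        n_possible = max(0, len(read.sequence) - k)
        n_emitted = 0
        for rec in _read_window_records(read.sequence, k):
            buf += rec.to_bytes(width, "big")
            n_emitted += 1
            if len(buf) >= (4 << 20):
                sink.write(bytes(buf))
                buf.clear()
        count += n_emitted
        skipped += n_possible - n_emitted
    if buf:
        sink.write(bytes(buf))
    if skipped:
        logger.info("skipped %d windows containing ambiguous bases", skipped)
    return count


def reduce_multiplicity(
    sorted_records: Iterable[bytes], k: int
) -> list[tuple[int, int, int, int, int]]:
    """Collapse a sorted record stream into (u, v, h1, h2, multiplicity)
    tuples, one per distinct key, in key order."""
    out: list[tuple[int, int, int, int, int]] = []
    prev: bytes | None = None
    mult = 0
    for rec in sorted_records:
        if rec == prev:
            mult += 1
        else:
            if prev is not None:
                out.append((*unpack_record(int.from_bytes(prev, "big"), k), mult))
            prev = rec
            mult = 1
    if prev is not None:
        out.append((*unpack_record(int.from_bytes(prev, "big"), k), mult))
    return out


def collect_vertices(
    edge_tuples: Sequence[tuple[int, int, int, int, int]], k: int
) -> tuple[list[KMolecule], dict[int, int]]:
    """Unique canonical endpoint codes, sorted, with dense ids by rank."""
    if not edge_tuples:
        return [], {}
    codes = sorted({t[0] for t in edge_tuples} | {t[1] for t in edge_tuples})
    molecules = []
    code_to_id = {}
    for i, c in enumerate(codes):
        seq = EncodedSeq(k, c)
        molecules.append(KMolecule(seq, reverse_complement(seq), i))
        code_to_id[c] = i
    return molecules, code_to_id


def build_adjacency(edges: Sequence[CanonicalEdge]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for i, e in enumerate(edges):
        adj.setdefault(e.u, []).append(i)
        if e.v != e.u:
            adj.setdefault(e.v, []).append(i)
    return adj


@dataclass
class BiGraph:
    """Bi-directed de Bruijn graph: sorted k-molecule vertices, canonical
    edge list, adjacency index.

    ``names`` carries a stable integer name per vertex (the dense id for
    built graphs; the min-endpoint convention after compaction).  For
    compacted graphs vertex labels are unitig strings rather than k-mers,
    but ``k`` is retained because adjacent labels still overlap by k−1.
    """

    k: int
    vertices: list[KMolecule]
    edges: list[CanonicalEdge]
    adjacency: dict[int, list[int]] = field(default_factory=dict)
    names: list[int] = field(default_factory=list)
    compacted: bool = False
    window_count: int = 0
    skipped_windows: int = 0
    cycle_report: object = None
    telemetry: Optional[SortTelemetry] = None

    def __post_init__(self):
        if not self.names:
            self.names = list(range(len(self.vertices)))
        if not self.adjacency and self.edges:
            self.adjacency = build_adjacency(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def label(self, vid: int) -> str:
        return self.vertices[vid].canonical_str

    def vertex_by_label(self, label: str) -> Optional[int]:
        canon = min(label, _rc_str(label))
        for i, m in enumerate(self.vertices):
            if m.canonical_str == canon:
                return i
        return None

    def edge_keys(self) -> list[tuple]:
        return [
            (self.label(e.u), self.label(e.v), e.h1.symbol, e.h2.symbol, e.multiplicity)
            for e in self.edges
        ]

    @classmethod
    def from_labelled_edges(
        cls,
        k: int,
        rows: Sequence[tuple[str, str, Head, Head, int]],
        extra_vertices: Sequence[str] = (),
        compacted: bool = False,
    ) -> "BiGraph":
        """Assemble a graph from labelled edge rows (tests, file readers).

        Labels are canonicalised (the smaller of label and its reverse
        complement) and rows are endpoint-normalised and sorted.
        """
        labels = {min(x, _rc_str(x)) for r in rows for x in (r[0], r[1])}
        labels |= {min(x, _rc_str(x)) for x in extra_vertices}
        ordered = sorted(labels)
        idx = {lab: i for i, lab in enumerate(ordered)}
        vertices = [
            KMolecule(encode(lab), reverse_complement(encode(lab)), i)
            for i, lab in enumerate(ordered)
        ]
        edges = []
        for ul, vl, h1, h2, mult in rows:
            u, v = idx[min(ul, _rc_str(ul))], idx[min(vl, _rc_str(vl))]
            if u > v:
                u, v, h1, h2 = v, u, h2.flip(), h1.flip()
            if u == v and h1 is Head.REV and h2 is Head.REV:
                h1 = h2 = Head.FWD
            edges.append(CanonicalEdge(u, v, h1, h2, mult))
        edges.sort(key=CanonicalEdge.key)
        merged: list[CanonicalEdge] = []
        for e in edges:
            if merged and merged[-1].key() == e.key():
                merged[-1].multiplicity += e.multiplicity
            else:
                merged.append(e)
        return cls(k=k, vertices=vertices, edges=merged, compacted=compacted,
                   window_count=sum(e.multiplicity for e in merged))


def _rc_str(s: str) -> str:
    from .codec import reverse_complement_str

    return reverse_complement_str(s)


def _sorted_record_stream_memory(blob: bytes, width: int) -> Iterator[bytes]:
    sorted_blob = sort_bytes_blob(blob, width)
    for i in range(0, len(sorted_blob), width):
        yield sorted_blob[i : i + width]


def build_graph(
    rs: ReadSet,
    k: int,
    mode: str = "auto",
    cfg: Optional[SortConfig] = None,
    min_multiplicity: int = 1,
    include_rc: bool = True,
) -> BiGraph:
    """Full pipeline: R* windows → records → sort → reduce → vertices →
    adjacency.  ``mode`` picks the in-memory radix path, the external merge
    path, or auto-selects by estimated record bytes against the budget.
    Results are identical across modes.

    ``include_rc=False`` skips adding reverse complements (for callers that
    already hold R*).
    """
    require_odd_k(k)
    cfg = cfg or SortConfig()
    if mode not in ("auto", "memory", "external"):
        raise ValueError(f"unknown mode {mode!r}")
    rstar = with_reverse_complements(rs) if include_rc else rs

    width = record_width(k)
    est_windows = sum(max(0, len(r.sequence) - k) for r in rstar.reads)
    if mode == "auto":
        mode = "external" if est_windows * width > cfg.memory_budget_bytes // 2 else "memory"

    telemetry = SortTelemetry()
    if est_windows == 0:
        logger.warning("no read admits a %d-mer window; graph is empty", k + 1)
        return BiGraph(k=k, vertices=[], edges=[], telemetry=telemetry)

    if mode == "memory":
        buf = bytearray()

        class _Buf:
            def write(self, b):
                buf.extend(b)

        count = emit_edge_records(rstar, k, _Buf())
        telemetry.note(len(buf))
        stream = _sorted_record_stream_memory(bytes(buf), width)
        tuples = reduce_multiplicity(stream, k)
    else:
        tmp_root = Path(cfg.tmp_dir) if cfg.tmp_dir else Path(tempfile.gettempdir())
        tmp_root.mkdir(parents=True, exist_ok=True)
        with tempfile.NamedTemporaryFile(
            prefix="bidbg-records-", dir=tmp_root, delete=False
        ) as fh:
            count = emit_edge_records(rstar, k, fh)
            rec_path = Path(fh.name)
        try:
            recfile = RecordFile.from_path(rec_path, width)
            sorted_file = external_sort(recfile, cfg, telemetry=telemetry)
            tuples = reduce_multiplicity(sorted_file.iter_records(cfg.block_bytes), k)
            sorted_file.path.unlink(missing_ok=True)
        finally:
            rec_path.unlink(missing_ok=True)

    skipped = est_windows - count
    if min_multiplicity > 1:
        tuples = [t for t in tuples if t[4] >= min_multiplicity]
    molecules, code_to_id = collect_vertices(tuples, k)
    edges = [
        CanonicalEdge(code_to_id[u], code_to_id[v], Head(h1), Head(h2), mult)
        for (u, v, h1, h2, mult) in tuples
    ]
    return BiGraph(
        k=k,
        vertices=molecules,
        edges=edges,
        window_count=count,
        skipped_windows=skipped,
        telemetry=telemetry,
    )
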