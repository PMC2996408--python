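"""Serialisation of bi-directed graphs: canonical TSV edge lists and GFA1.

TSV dialect: a header line ``#k=<k>`` (plus ``#compacted=1`` for compacted
graphs), then one line per edge ``u_label<TAB>v_label<TAB>h1<TAB>h2<TAB>mult``
with heads written ``>`` (FWD) and ``<`` (REV), rows in canonical sort
order.  Vertices that touch no edge are declared on ``V<TAB>label`` lines so
the round trip is lossless.  Labels are decoded strings, human-diffable.

GFA1: ``H VN:Z:1.0``, one S line per molecule (canonical label), one L line
per edge with FWD→``+`` and REV→``-`` and the overlap written as
``<k-1>M`` (adjacent labels overlap by k−1 both before and after
compaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .build import BiGraph, Head


class GraphFileError(ValueError):
    """Malformed graph file."""


def _label_canonical_row(g: BiGraph, e) -> tuple[str, str, Head, Head, int]:
    """Edge as a label-ordered row (u_label <= v_label), so the file form is
    independent of the graph's internal vertex numbering."""
    ul, vl, h1, h2 = g.label(e.u), g.label(e.v), e.h1, e.h2
    if ul > vl:
        ul, vl, h1, h2 = vl, ul, h2.flip(), h1.flip()
    if ul == vl and h1 is Head.REV and h2 is Head.REV:
        h1 = h2 = Head.FWD
    return ul, vl, h1, h2, e.multiplicity


def write_edges_tsv(g: BiGraph, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={g.k}\n")
        if g.compacted:
            fh.write("#compacted=1\n")
        used = {e.u for e in g.edges} | {e.v for e in g.edges}
        for lab in sorted(g.label(v) for v in range(g.n_vertices) if v not in used):
            fh.write(f"V\t{lab}\n")
        rows = sorted(
            (_label_canonical_row(g, e) for e in g.edges),
            key=lambda r: (r[0], r[1], int(r[2]), int(r[3])),
        )
        for ul, vl, h1, h2, mult in rows:
            fh.write(f"{ul}\t{vl}\t{h1.symbol}\t{h2.symbol}\t{mult}\n")


def read_edges_tsv(path: Union[str, Path]) -> BiGraph:
    path = Path(path)
    k = None
    compacted = False
    rows: list[tuple[str, str, Head, Head, int]] = []
    isolated: list[str] = []
    prev_key = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "k":
                    k = int(val)
                elif key == "compacted":
                    compacted = val == "1"
                continue
            fields = line.split("\t")
            if fields[0] == "V":
                if len(fields) != 2:
                    raise GraphFileError(f"{path}:{lineno}: malformed vertex line")
                isolated.append(fields[1])
                continue
            if len(fields) != 5:
                raise GraphFileError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            ul, vl, s1, s2, mult = fields
            try:
                h1, h2 = Head.from_symbol(s1), Head.from_symbol(s2)
            except ValueError as exc:
                raise GraphFileError(f"{path}:{lineno}: {exc}") from exc
            key = (ul, vl, int(h1), int(h2))
            if prev_key is not None and key <= prev_key:
                raise GraphFileError(
                    f"{path}:{lineno}: rows not in canonical sort order"
                )
            prev_key = key
            rows.append((ul, vl, h1, h2, int(mult)))
    if k is None:
        raise GraphFileError(f"{path}: missing '#k=' header")
    g = BiGraph.from_labelled_edges(k, rows, extra_vertices=isolated,
                                    compacted=compacted)
    return g


def segment_name(g: BiGraph, vid: int) -> str:
    return f"m{g.names[vid]}"


def write_gfa(g: BiGraph, path: Union[str, Path]) -> None:
    ov = g.k - 1
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for vid in range(g.n_vertices):
            fh.write(f"S\t{segment_name(g, vid)}\t{g.label(vid)}\n")
        for e in g.edges:
            o1 = "+" if e.h1 is Head.FWD else "-"
            o2 = "+" if e.h2 is Head.FWD else "-"
            fh.write(
                f"L\t{segment_name(g, e.u)}\t{o1}\t{segment_name(g, e.v)}\t{o2}"
                f"\t{ov}M\n"
            )


@dataclass
class GraphStats:
    k: int
    vertex_count: int
    edge_count: int
    total_multiplicity: int
    self_loop_count: int
    compacted: bool
    label_length_histogram: dict[int, int] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"k={self.k} vertices={self.vertex_count} edges={self.edge_count} "
            f"total_mult={self.total_multiplicity} self_loops={self.self_loop_count} "
            f"compacted={int(self.compacted)}"
        )


def stats(g: BiGraph) -> GraphStats:
    hist: dict[int, int] = {}
    for m in g.vertices:
        hist[m.canonical.length] = hist.get(m.canonical.length, 0) + 1
    return GraphStats(
        k=g.k,
        vertex_count=g.n_vertices,
        edge_count=g.n_edges,
        total_multiplicity=sum(e.multiplicity for e in g.edges),
        self_loop_count=sum(1 for e in g.edges if e.u == e.v),
        compacted=g.compacted,
        label_length_histogram=dict(sorted(hist.items())),
    )
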