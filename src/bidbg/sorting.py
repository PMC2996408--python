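"""Fixed-width record sorting: in-memory LSD radix and external R-way merge.

Records are fixed-width big-endian byte strings, so lexicographic byte order
equals unsigned integer order.  The in-memory path is an LSD radix sort with
8-bit digits (one byte per pass).  The external path generates memory-sized
sorted runs, then merges them R at a time through B-byte block cursors under
an explicit memory budget M; pass count is 1 + ceil(log_R(runs)).  Buffer
accounting is instrumented so tests can assert the budget is honoured
without OS probing.
"""

from __future__ import annotations

import heapq
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np


@dataclass
class RecordFile:
    """A file of fixed-width binary records."""

    path: Path
    record_width: int
    count: int

    @classmethod
    def from_path(cls, path: Union[str, Path], record_width: int) -> "RecordFile":
        path = Path(path)
        size = path.stat().st_size
        if size % record_width:
            raise ValueError(
                f"{path}: size {size} is not a multiple of record width {record_width}"
            )
        return cls(path, record_width, size // record_width)

    def read_all(self) -> bytes:
        return self.path.read_bytes()

    def iter_records(self, block_bytes: int = 1 << 20) -> Iterator[bytes]:
        w = self.record_width
        per_block = max(1, block_bytes // w) * w
        with open(self.path, "rb") as fh:
            while True:
                buf = fh.read(per_block)
                if not buf:
                    return
                for i in range(0, len(buf), w):
                    yield buf[i : i + w]


@dataclass
class SortConfig:
    """External-sort parameters: memory budget M, block size B.

    Fan-in R is derived as max(2, floor(M/B) - 1): R input cursors plus one
    output block must fit in M.
    """

    memory_budget_bytes: int = 256 << 20
    block_bytes: int = 256 << 10
    tmp_dir: Union[str, Path, None] = None

    def __post_init__(self):
        if self.block_bytes < 1:
            raise ValueError("block_bytes must be positive")
        if self.memory_budget_bytes < 2 * self.block_bytes:
            raise ValueError("memory budget must be at least 2 blocks (M >= 2B)")

    @property
    def fan_in(self) -> int:
        return max(2, self.memory_budget_bytes // self.block_bytes - 1)


@dataclass
class SortTelemetry:
    """Instrumented accounting of an external sort."""

    runs: int = 0
    merge_passes: int = 0
    peak_payload_bytes: int = 0
    phases: list[int] = field(default_factory=list)

    @property
    def total_passes(self) -> int:
        return (1 if self.runs else 0) + self.merge_passes

    def note(self, payload: int) -> None:
        if payload > self.peak_payload_bytes:
            self.peak_payload_bytes = payload


def _as_byte_matrix(records: Sequence[int], key_bits: int) -> np.ndarray:
    width = max(1, (key_bits + 7) // 8)
    buf = bytearray()
    for r in records:
        buf += int(r).to_bytes(width, "big")
    return np.frombuffer(bytes(buf), dtype=np.uint8).reshape(len(records), width)


def radix_sort_bytes(mat: np.ndarray) -> np.ndarray:
    """Stable LSD radix sort of an (N, W) uint8 matrix, one byte per pass.

    Each pass applies a stable ordering on one digit column, least
    significant first; numpy's stable integer argsort (itself a counting/
    radix sort) supplies the per-digit permutation.
    """
    if mat.ndim != 2:
        raise ValueError("expected an (N, W) byte matrix")
    n, width = mat.shape
    if n <= 1:
        return mat.copy()
    order = np.arange(n)
    for col in range(width - 1, -1, -1):
        digits = mat[order, col]
        order = order[np.argsort(digits, kind="stable")]
    return mat[order]


def radix_sort(records: Sequence[int], key_bits: int) -> list[int]:
    """Stable LSD radix sort of unsigned integers below 2**key_bits."""
    if key_bits < 1:
        raise ValueError("key_bits must be >= 1")
    records = list(records)
    if any(r < 0 or r >> key_bits for r in records):
        raise ValueError(f"record out of range for key_bits={key_bits}")
    if len(records) <= 1:
        return records
    width = max(1, (key_bits + 7) // 8)
    mat = _as_byte_matrix(records, key_bits)
    out = radix_sort_bytes(mat)
    packed = out.tobytes()
    return [
        int.from_bytes(packed[i : i + width], "big")
        for i in range(0, len(packed), width)
    ]


def sort_bytes_blob(blob: bytes, record_width: int) -> bytes:
    """Radix-sort a packed blob of fixed-width records; returns sorted blob."""
    if len(blob) % record_width:
        raise ValueError("blob size not a multiple of record width")
    n = len(blob) // record_width
    if n <= 1:
        return blob
    mat = np.frombuffer(blob, dtype=np.uint8).reshape(n, record_width)
    return radix_sort_bytes(mat).tobytes()


class _RunCursor:
    """Buffered reader over one sorted run, B bytes at a time."""

    __slots__ = ("fh", "width", "block", "buf", "pos")

    def __init__(self, path: Path, record_width: int, block_bytes: int):
        self.fh = open(path, "rb")
        self.width = record_width
        self.block = max(record_width, block_bytes // record_width * record_width)
        self.buf = b""
        self.pos = 0

    def next_record(self) -> bytes | None:
        if self.pos >= len(self.buf):
            self.buf = self.fh.read(self.block)
            self.pos = 0
            if not self.buf:
                self.fh.close()
                return None
        rec = self.buf[self.pos : self.pos + self.width]
        self.pos += self.width
        return rec


def _merge_runs(
    run_paths: list[Path],
    out_path: Path,
    record_width: int,
    cfg: SortConfig,
    telemetry: SortTelemetry,
) -> None:
    cursors = [_RunCursor(p, record_width, cfg.block_bytes) for p in run_paths]
    # resident payload: one block per input cursor plus one output block
    telemetry.note((len(cursors) + 1) * cfg.block_bytes)
    heap: list[tuple[bytes, int]] = []
    for i, c in enumerate(cursors):
        rec = c.next_record()
        if rec is not None:
            heap.append((rec, i))  # ties broken by run index: deterministic
    heapq.heapify(heap)
    out_block = bytearray()
    with open(out_path, "wb") as out:
        while heap:
            rec, i = heapq.heappop(heap)
            out_block += rec
            if len(out_block) >= cfg.block_bytes:
                out.write(out_block)
                out_block.clear()
            nxt = cursors[i].next_record()
            if nxt is not None:
                heapq.heappush(heap, (nxt, i))
        out.write(out_block)


def external_sort(
    infile: RecordFile,
    cfg: SortConfig,
    out_path: Union[str, Path, None] = None,
    telemetry: SortTelemetry | None = None,
) -> RecordFile:
    """External R-way merge sort of a fixed-width record file.

    Run generation loads at most M bytes of payload at a time and radix-sorts
    each chunk in memory; merging combines R runs per pass until one remains.
    Temporary files live under cfg.tmp_dir and are removed on success.
    """
    telemetry = telemetry if telemetry is not None else SortTelemetry()
    w = infile.record_width
    tmp_root = Path(cfg.tmp_dir) if cfg.tmp_dir else Path(tempfile.gettempdir())
    tmp_root.mkdir(parents=True, exist_ok=True)
    work = Path(tempfile.mkdtemp(prefix="bidbg-sort-", dir=tmp_root))
    out_path = Path(out_path) if out_path else work.parent / (work.name + ".sorted")

    chunk_records = max(1, cfg.memory_budget_bytes // w)
    runs: list[Path] = []
    try:
        with open(infile.path, "rb") as fh:
            while True:
                blob = fh.read(chunk_records * w)
                if not blob:
                    break
                telemetry.note(len(blob))
                sorted_blob = sort_bytes_blob(blob, w)
                run = work / f"run-{len(runs):06d}.bin"
                run.write_bytes(sorted_blob)
                runs.append(run)
        telemetry.runs = len(runs)

        if not runs:
            out_path.write_bytes(b"")
        elif len(runs) == 1:
            shutil.move(str(runs[0]), out_path)
        else:
            level = runs
            gen = 0
            while len(level) > 1:
                telemetry.merge_passes += 1
                nxt: list[Path] = []
                for i in range(0, len(level), cfg.fan_in):
                    group = level[i : i + cfg.fan_in]
                    tgt = work / f"merge-{gen}-{len(nxt):06d}.bin"
                    if len(group) == 1:
                        shutil.move(str(group[0]), tgt)
                    else:
                        _merge_runs(group, tgt, w, cfg, telemetry)
                        for p in group:
                            p.unlink()
                    nxt.append(tgt)
                level = nxt
                gen += 1
            shutil.move(str(level[0]), out_path)
    except OSError as exc:
        raise OSError(f"external sort failed under {work}: {exc}") from exc
    finally:
        shutil.rmtree(work, ignore_errors=True)
    return RecordFile.from_path(out_path, w)
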