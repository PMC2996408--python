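"""Read FASTA/FASTQ inputs and simulate genomes / read sets.

The simulator exists so every pipeline stage is testable without downloads:
uniform random genomes, uniformly placed substitution-error reads, optional
reverse-complementing of a fraction of reads, optional circular genomes.
All randomness flows from one seed through named sub-streams (positions,
strands, errors) so adding one feature does not shift another's stream.
"""

from __future__ import annotations

import gzip
import io
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from Bio import SeqIO

from .codec import reverse_complement_str

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class SequenceFileError(ValueError):
    """Malformed or unrecognisable sequence file."""


@dataclass(frozen=True)
class Read:
    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.name!r} has an empty sequence")


@dataclass
class ReadSetStats:
    reads: int = 0
    bases: int = 0
    skipped_windows: int = 0


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    stats: ReadSetStats = field(default_factory=ReadSetStats)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], prefix: str = "read") -> "ReadSet":
        reads = [Read(f"{prefix}{i}", s) for i, s in enumerate(seqs)]
        return cls(reads, ReadSetStats(len(reads), sum(len(r.sequence) for r in reads)))


def _open_maybe_gzip(path: Path) -> io.TextIOWrapper:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _detect_format(path: Path, handle: io.TextIOWrapper) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if any(s in (".fa", ".fasta", ".fna") for s in suffixes):
        return "fasta"
    if any(s in (".fq", ".fastq") for s in suffixes):
        return "fastq"
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceFileError(
        f"{path}: cannot detect format (expected '>' or '@' as first byte)"
    )


def read_sequences(
    path: Union[str, Path],
    format: str = "auto",
    logger=None,
) -> ReadSet:
    """Load all records of a FASTA/FASTQ file (plain or gzip) in file order.

    FASTQ qualities are dropped.  Malformed records raise
    :class:`SequenceFileError` naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    handle = _open_maybe_gzip(path)
    fmt = format if format in ("fasta", "fastq") else _detect_format(path, handle)
    reads: list[Read] = []
    bases = 0
    try:
        for i, rec in enumerate(SeqIO.parse(handle, fmt)):
            seq = str(rec.seq)
            if not seq:
                raise SequenceFileError(f"{path}: record {i + 1} ({rec.id}) is empty")
            reads.append(Read(rec.id, seq))
            bases += len(seq)
    except ValueError as exc:  # biopython signals malformed records this way
        raise SequenceFileError(
            f"{path}: malformed {fmt} near record {len(reads) + 1}: {exc}"
        ) from exc
    finally:
        handle.close()
    if not reads and logger is not None:
        logger.warning("%s: empty input file", path)
    return ReadSet(reads, ReadSetStats(len(reads), bases))


def read_many(paths: Iterable[Union[str, Path]], format: str = "auto") -> ReadSet:
    """Concatenate several input files into one ReadSet."""
    out = ReadSet()
    for p in paths:
        rs = read_sequences(p, format=format)
        out.reads.extend(rs.reads)
        out.stats.reads += rs.stats.reads
        out.stats.bases += rs.stats.bases
    return out


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def rc_read(seq: str) -> str:
    """Reverse complement tolerating ambiguous bases (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def with_reverse_complements(rs: ReadSet) -> ReadSet:
    """Return R* = R_f ∪ R̄_f: the input reads plus all reverse complements."""
    reads = list(rs.reads)
    reads.extend(Read(f"{r.name}/rc", rc_read(r.sequence)) for r in rs.reads)
    return ReadSet(reads, ReadSetStats(2 * rs.stats.reads, 2 * rs.stats.bases))


def write_fasta(rs: ReadSet, path: Union[str, Path], width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in rs.reads:
            fh.write(f">{r.name}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def _stream(seed: int, purpose: str) -> np.random.Generator:
    """Named child PRNG stream: one global seed, one stream per purpose."""
    key = zlib.crc32(purpose.encode())
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, key))))


def simulate_genome(length: int, circular: bool = False, seed: int = 0) -> str:
    """Uniform random ACGT string of the given length (circularity only
    affects downstream read placement, not the string itself)."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = _stream(seed, "genome")
    return rng.choice(_ALPHABET, size=length).tobytes().decode()


def simulate_genome_unique_kmers(length: int, k: int, seed: int = 0,
                                 max_tries: int = 50) -> str:
    """Random genome screened so all its k-mers (and their reverse
    complements) are distinct -- i.e. the graph of the genome is one chain."""
    for attempt in range(max_tries):
        g = simulate_genome(length, seed=seed + 1000003 * attempt)
        seen: set[str] = set()
        ok = True
        for i in range(length - k + 1):
            km = g[i : i + k]
            rc = reverse_complement_str(km)
            if km in seen or rc in seen:
                ok = False
                break
            seen.add(km)
        if ok:
            return g
    raise RuntimeError(f"no genome of length {length} with unique {k}-mers found")


def simulate_reads(
    genome: str,
    read_length: int,
    coverage: float,
    error_rate: float = 0.0,
    rc_fraction: float = 0.0,
    circular: bool = False,
    seed: int = 0,
    logger=None,
) -> ReadSet:
    """Draw ceil(coverage*|genome|/read_length) uniform-start reads.

    Starts wrap around iff ``circular``; on a linear genome reads running off
    the end are truncated (count logged).  Each read is independently
    reverse-complemented with probability ``rc_fraction``; substitution
    errors are applied at per-base rate ``error_rate``.
    """
    glen = len(genome)
    if not circular and read_length > glen:
        raise ValueError("read_length exceeds genome length for a linear genome")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    n_reads = int(np.ceil(coverage * glen / read_length))
    pos_rng = _stream(seed, "positions")
    strand_rng = _stream(seed, "strands")
    err_rng = _stream(seed, "errors")
    doubled = genome + genome  # cheap wrap-around view
    starts = pos_rng.integers(0, glen, size=n_reads)
    flips = strand_rng.random(n_reads) < rc_fraction
    reads: list[Read] = []
    truncated = 0
    for i in range(n_reads):
        s = int(starts[i])
        if circular:
            seq = doubled[s : s + read_length]
        else:
            seq = genome[s : s + read_length]
            if len(seq) < read_length:
                truncated += 1
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(err_rng.random(len(arr)) < error_rate)
            if hits.size:
                # substitute with one of the three *other* bases
                cur = arr[hits]
                idx = np.searchsorted(_ALPHABET, cur)
                shift = err_rng.integers(1, 4, size=hits.size)
                arr[hits] = _ALPHABET[(idx + shift) % 4]
            seq = arr.tobytes().decode()
        if flips[i]:
            seq = reverse_complement_str(seq)
        reads.append(Read(f"sim{i}", seq))
    if truncated and logger is not None:
        logger.info("%d reads truncated at the linear genome end", truncated)
    return ReadSet(reads, ReadSetStats(len(reads), sum(len(r.sequence) for r in reads)))


def tiling_reads(genome: str, read_length: int, step: int,
                 circular: bool = False) -> ReadSet:
    """Deterministic error-free reads tiling the genome.

    With step <= read_length - k, every (k+1)-mer of the genome appears in
    some read, which is what full-reconstruction compaction tests need.
    """
    glen = len(genome)
    doubled = genome + genome
    seqs = []
    if circular:
        for s in range(0, glen, step):
            seqs.append(doubled[s : s + read_length])
    else:
        s = 0
        while True:
            seqs.append(genome[s : s + read_length])
            if s + read_length >= glen:
                break
            s = min(s + step, glen - read_length)
    return ReadSet.from_sequences(seqs, prefix="tile")


def write_provenance(path: Union[str, Path], **params) -> None:
    """Sidecar JSON recording simulator parameters and seed."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
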