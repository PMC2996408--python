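"""Fixed-width integer encoding of DNA and canonical-form arithmetic.

Every DNA string is packed 2 bits per base (A=0, C=1, G=2, T=3) with the
leftmost base in the most significant bits, so integer comparison of two
equal-length codes is exactly lexicographic comparison of the strings.
A *k-molecule* pairs a canonical k-mer (the lexicographically smaller of a
k-mer and its reverse complement) with its reverse complement; one molecule
models both strands of the DNA at that position.  k is required to be odd so
that no k-mer equals its own reverse complement and the canonical choice is
strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_TO_BASE = "ACGT"


class InvalidBaseError(ValueError):
    """Raised when a sequence contains a character outside A/C/G/T.

    Carries the offending character and its 1-based position.
    """

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid base {char!r} at position {position}: only A/C/G/T accepted"
        )


class EvenKError(ValueError):
    """Raised for even k: k must be odd so canonical k-mers are strict."""

    def __init__(self, k: int):
        self.k = k
        super().__init__(
            f"k={k} is even; k must be odd so that a k-mer never equals its "
            "own reverse complement"
        )


def require_odd_k(k: int) -> int:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        raise EvenKError(k)
    return k


@dataclass(frozen=True, order=True)
class EncodedSeq:
    """A DNA string packed into an unsigned integer, 2 bits per base.

    Ordering is (length, code); for equal lengths integer order on ``code``
    equals lexicographic order on the decoded string.
    """

    length: int
    code: int

    def __post_init__(self):
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if not 0 <= self.code < (1 << (2 * self.length)):
            raise ValueError(
                f"code {self.code} out of range for length {self.length}"
            )

    def __str__(self) -> str:
        return decode(self)

    def __len__(self) -> int:
        return self.length


def encode(s: str) -> EncodedSeq:
    """Pack a DNA string; lowercase accepted, anything but ACGT rejected."""
    code = 0
    for i, ch in enumerate(s.upper()):
        b = _BASE_TO_BITS.get(ch)
        if b is None:
            raise InvalidBaseError(s[i], i + 1)
        code = (code << 2) | b
    return EncodedSeq(len(s), code)


def decode(seq: EncodedSeq) -> str:
    out = []
    code = seq.code
    for _ in range(seq.length):
        out.append(_BITS_TO_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def rc_code(code: int, length: int) -> int:
    """Reverse complement on the packed representation.

    Complement is bitwise NOT of each 2-bit base (A<->T, C<->G); reversal
    walks the bases back to front.
    """
    out = 0
    for _ in range(length):
        out = (out << 2) | (~code & 3)
        code >>= 2
    return out


def reverse_complement(seq: EncodedSeq) -> EncodedSeq:
    return EncodedSeq(seq.length, rc_code(seq.code, seq.length))


def reverse_complement_str(s: str) -> str:
    """Reverse complement of a plain string (convenience for I/O layers)."""
    return decode(reverse_complement(encode(s)))


def canonical_form(seq: EncodedSeq) -> tuple[EncodedSeq, bool]:
    """Return (canonical form, flipped): the smaller of seq and its reverse
    complement, and whether the reverse complement won."""
    rc = reverse_complement(seq)
    if rc.code < seq.code:
        return rc, True
    return seq, False


@dataclass(frozen=True)
class KMolecule:
    """A graph vertex: canonical k-mer paired with its reverse complement.

    ``id`` is the dense ordinal assigned after vertex sorting (None before).
    For compacted graphs the "k-mer" generalises to an arbitrary-length label;
    ``canonical <= noncanonical`` still holds, and a label equal to its own
    reverse complement is flagged self-complementary.
    """

    canonical: EncodedSeq
    noncanonical: EncodedSeq
    id: Optional[int] = None

    @property
    def canonical_str(self) -> str:
        return decode(self.canonical)

    @property
    def noncanonical_str(self) -> str:
        return decode(self.noncanonical)

    @property
    def self_complementary(self) -> bool:
        return self.canonical == self.noncanonical

    def strand(self, plus: bool) -> EncodedSeq:
        return self.canonical if plus else self.noncanonical


def kmolecule(seq: EncodedSeq, id: Optional[int] = None) -> KMolecule:
    """Build the k-molecule of a k-mer (odd length enforced)."""
    require_odd_k(seq.length)
    canon, _ = canonical_form(seq)
    return KMolecule(canon, reverse_complement(canon), id)


def window_k1mers(read: str, k: int) -> Iterator[EncodedSeq]:
    """Yield every (k+1)-mer window of ``read`` whose bases are all ACGT.

    Windows containing any other character are skipped silently; reads
    shorter than k+1 yield nothing.  A rolling 2-bit encoding keeps this
    O(1) per window.
    """
    require_odd_k(k)
    w = k + 1
    mask = (1 << (2 * w)) - 1
    code = 0
    run = 0  # length of current ACGT run ending here
    for ch in read.upper():
        b = _BASE_TO_BITS.get(ch)
        if b is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask
        run += 1
        if run >= w:
            yield EncodedSeq(w, code)


def count_valid_windows(read: str, k: int) -> int:
    """Number of (k+1)-windows window_k1mers would yield for this read."""
    return sum(1 for _ in window_k1mers(read, k))
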