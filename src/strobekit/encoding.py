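"""Sequence input and 2-bit nucleotide encoding.

DNA over the alphabet {A, C, G, T} is packed two bits per base
(A=00, C=01, G=10, T=11). An l-mer is stored as ``ceil(l/32)``
64-bit words, most-significant word first, with the first base in
the most significant occupied bit pair, so numeric order of the
packed value equals lexicographic order of the l-mer.

Characters outside ACGT (e.g. N) are removed before encoding:
all downstream coordinates refer to the cleaned sequence.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "EncodedSequence",
    "StrobeValue",
    "FastaFormatError",
    "read_fasta",
    "clean_sequence",
    "encode",
    "decode",
    "lmer_at",
    "lmer_words",
    "n_words",
]

_BASES = b"ACGT"

# uppercase fold + deletion of everything outside acgtACGT, done bytewise
_UPPER = bytes(range(256)).upper()
_DELETE = bytes(c for c in range(256) if _UPPER[c] not in _BASES)

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_BASES):
    _CODE_LUT[_c] = _i


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass
class EncodedSequence:
    """A cleaned, 2-bit encoded nucleotide sequence.

    Attributes
    ----------
    name : str
        Record identifier.
    codes : numpy.ndarray
        uint8 array of symbols in {0, 1, 2, 3} for {A, C, G, T}.
    """

    name: str
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.size and self.codes.max() > 3:
            raise ValueError("codes must be in {0,1,2,3}")

    @property
    def length(self) -> int:
        return int(self.codes.size)

    def __len__(self) -> int:
        return self.length

    def decode(self) -> str:
        """Return the ACGT string this object encodes."""
        return bytes(np.frombuffer(_BASES, dtype=np.uint8)[self.codes]).decode()


@dataclass(frozen=True)
class StrobeValue:
    """Packed integer value of one l-mer.

    ``words`` holds ``ceil(l/32)`` unsigned 64-bit words, most
    significant first; the 2l encoding bits are right-aligned.
    """

    l: int
    words: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if len(self.words) != n_words(self.l):
            raise ValueError(
                f"expected {n_words(self.l)} words for l={self.l}, got {len(self.words)}"
            )
        used_top = 2 * self.l - 64 * (len(self.words) - 1)  # bits used in words[0]
        if any(not (0 <= w < 1 << 64) for w in self.words):
            raise ValueError("words must be unsigned 64-bit")
        if self.words[0] >> used_top:
            raise ValueError("unused high bits must be zero")

    @property
    def value(self) -> int:
        """The packed value as one arbitrary-precision integer."""
        v = 0
        for w in self.words:
            v = (v << 64) | w
        return v


def n_words(l: int) -> int:
    """Number of 64-bit words needed for an l-mer (32 bases per word)."""
    return (l + 31) // 32


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(identifier, raw sequence)`` records from a FASTA file.

    Plain or gzip-compressed files are accepted. The raw string keeps
    case and ambiguity codes; run :func:`clean_sequence` before encoding.
    """
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    # Bio.SeqIO silently skips text before the first header; reject it
    # explicitly so malformed files fail loudly with a line number.
    with opener(path, "rt") as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"sequence data before any FASTA header at line {lineno}"
                    )
                if not line[1:].strip():
                    raise FastaFormatError(f"empty FASTA header at line {lineno}")
                break
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise FastaFormatError(f"empty FASTA header in record {record.description!r}")
            yield record.id, str(record.seq)


def clean_sequence(raw: str) -> str:
    """Uppercase and drop every character outside ACGT, keeping order."""
    return raw.encode("ascii", errors="replace").translate(_UPPER, _DELETE).decode()


def encode(cleaned: str, name: str = "") -> EncodedSequence:
    """Encode an ACGT-only string as 2-bit symbols.

    Raises ``ValueError`` if any character outside ACGT remains.
    """
    arr = np.frombuffer(cleaned.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[arr]
    if codes.size and codes.max() == 255:
        bad = cleaned[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r}; run clean_sequence first")
    return EncodedSequence(name=name, codes=codes)


def decode(seq: EncodedSequence) -> str:
    """Inverse of :func:`encode`."""
    return seq.decode()


def lmer_at(seq: EncodedSequence, pos: int, l: int) -> StrobeValue:
    """Packed value of the l-mer starting at 0-based ``pos``."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if pos < 0 or pos + l > seq.length:
        raise IndexError(f"l-mer [{pos}, {pos + l}) out of range for length {seq.length}")
    v = 0
    for c in seq.codes[pos : pos + l]:
        v = (v << 2) | int(c)
    nw = n_words(l)
    words = tuple((v >> (64 * (nw - 1 - i))) & ((1 << 64) - 1) for i in range(nw))
    return StrobeValue(l=l, words=words)


def lmer_words(seq: EncodedSequence | np.ndarray, l: int) -> np.ndarray:
    """Packed values of every l-mer, vectorized.

    Returns a ``(length - l + 1, ceil(l/32))`` uint64 array, most
    significant word first, matching :func:`lmer_at` position by
    position. Empty (0, nw) array when the sequence is too short.
    """
    codes = seq.codes if isinstance(seq, EncodedSequence) else np.asarray(seq, dtype=np.uint8)
    if l < 1:
        raise ValueError("l must be >= 1")
    nw = n_words(l)
    n = codes.size - l + 1
    if n <= 0:
        return np.empty((0, nw), dtype=np.uint64)
    out = np.empty((n, nw), dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    # bases per word: the first word takes the leading remainder, the rest 32 each
    first = l - 32 * (nw - 1)
    start = 0
    for wi, nbases in enumerate([first] + [32] * (nw - 1)):
        acc = np.zeros(n, dtype=np.uint64)
        for j in range(start, start + nbases):
            acc = (acc << np.uint64(2)) | codes64[j : j + n]
        out[:, wi] = acc
        start += nbases
    return out
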