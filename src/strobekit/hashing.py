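"""64-bit strobe hash functions.

Four schemes map a packed l-mer to a 64-bit pseudo-random value:

* ``NO`` — no hashing; the 2-bit encoding itself (multi-word values
  are XOR-folded to one word so the interface stays total).
* ``TW`` — the Thomas Wang invertible 64-bit integer mix (as used in
  minimap2-style seeding); single-word values only (l <= 32).
* ``XX`` — xxHash64 of the little-endian byte serialization.
* ``WY`` — a wyhash-style mum mixer (final_3 construction, seed 0)
  of the same serialization.

Hashing whitens the raw encoding so that window selection behaves
pseudo-randomly even on biased nucleotide composition. All functions
here are pure and deterministic; the batch (numpy) counterparts live
in :mod:`strobekit._vechash` and are cross-checked against these
scalar transcriptions in the test suite.
"""

from __future__ import annotations

import enum
from typing import Iterable

from .encoding import StrobeValue

__all__ = [
    "HashScheme",
    "IncompatibleSchemeError",
    "thomas_wang_64",
    "xxh64",
    "wyhash64",
    "serialize_words",
    "strobe_hash",
]

_M64 = (1 << 64) - 1


class IncompatibleSchemeError(ValueError):
    """A hash/link/width combination the scheme cannot accept."""


class HashScheme(str, enum.Enum):
    """Identifier of the per-strobe hash function."""

    NO = "NO"
    TW = "TW"
    XX = "XX"
    WY = "WY"

    @property
    def word_capacity(self) -> int | None:
        """Max strobe words accepted; None means unbounded."""
        return 1 if self is HashScheme.TW else None


def thomas_wang_64(x: int) -> int:
    """Thomas Wang's invertible 64-bit integer hash.

    Seven mixing steps, all arithmetic modulo 2**64.
    """
    x &= _M64
    x = (~x + (x << 21)) & _M64
    x = x ^ (x >> 24)
    x = (x + (x << 3) + (x << 8)) & _M64
    x = x ^ (x >> 14)
    x = (x + (x << 2) + (x << 4)) & _M64
    x = x ^ (x >> 28)
    x = (x + (x << 31)) & _M64
    return x


# ---------------------------------------------------------------------------
# xxHash64 (seedable, little-endian lane reads)

_XXP1 = 0x9E3779B185EBCA87
_XXP2 = 0xC2B2AE3D27D4EB4F
_XXP3 = 0x165667B19E3779F9
_XXP4 = 0x85EBCA77C2B2AE63
_XXP5 = 0x27D4EB2F165667C5


def _rotl(x: int, r: int) -> int:
    return ((x << r) | (x >> (64 - r))) & _M64


def _xx_round(acc: int, lane: int) -> int:
    return (_rotl((acc + lane * _XXP2) & _M64, 31) * _XXP1) & _M64


def _xx_merge(h: int, acc: int) -> int:
    return ((h ^ _xx_round(0, acc)) * _XXP1 + _XXP4) & _M64


def xxh64(data: bytes, seed: int = 0) -> int:
    """xxHash64 of a byte string."""
    n = len(data)
    p = 0
    if n >= 32:
        a1 = (seed + _XXP1 + _XXP2) & _M64
        a2 = (seed + _XXP2) & _M64
        a3 = seed & _M64
        a4 = (seed - _XXP1) & _M64
        while p + 32 <= n:
            a1 = _xx_round(a1, int.from_bytes(data[p : p + 8], "little"))
            a2 = _xx_round(a2, int.from_bytes(data[p + 8 : p + 16], "little"))
            a3 = _xx_round(a3, int.from_bytes(data[p + 16 : p + 24], "little"))
            a4 = _xx_round(a4, int.from_bytes(data[p + 24 : p + 32], "little"))
            p += 32
        h = (_rotl(a1, 1) + _rotl(a2, 7) + _rotl(a3, 12) + _rotl(a4, 18)) & _M64
        for acc in (a1, a2, a3, a4):
            h = _xx_merge(h, acc)
    else:
        h = (seed + _XXP5) & _M64
    h = (h + n) & _M64
    while p + 8 <= n:
        h ^= _xx_round(0, int.from_bytes(data[p : p + 8], "little"))
        h = (_rotl(h, 27) * _XXP1 + _XXP4) & _M64
        p += 8
    if p + 4 <= n:
        h ^= (int.from_bytes(data[p : p + 4], "little") * _XXP1) & _M64
        h = (_rotl(h, 23) * _XXP2 + _XXP3) & _M64
        p += 4
    while p < n:
        h ^= (data[p] * _XXP5) & _M64
        h = (_rotl(h, 11) * _XXP1) & _M64
        p += 1
    h ^= h >> 33
    h = (h * _XXP2) & _M64
    h ^= h >> 29
    h = (h * _XXP3) & _M64
    h ^= h >> 32
    return h


# ---------------------------------------------------------------------------
# wyhash (final_3 construction)

_WYP = (
    0xA0761D6478BD642F,
    0xE7037ED1A0B428DB,
    0x8EBC6AF09C88C6E3,
    0x589965CC75374CC3,
)


def _wymum(a: int, b: int) -> tuple[int, int]:
    r = a * b
    return r & _M64, (r >> 64) & _M64


def _wymix(a: int, b: int) -> int:
    lo, hi = _wymum(a, b)
    return lo ^ hi


def _wyr8(data: bytes, p: int) -> int:
    return int.from_bytes(data[p : p + 8], "little")


def _wyr4(data: bytes, p: int) -> int:
    return int.from_bytes(data[p : p + 4], "little")


def _wyr3(data: bytes, p: int, k: int) -> int:
    return (data[p] << 16) | (data[p + (k >> 1)] << 8) | data[p + k - 1]


def wyhash64(data: bytes, seed: int = 0) -> int:
    """wyhash (final_3 construction) of a byte string."""
    n = len(data)
    seed = (seed ^ _WYP[0]) & _M64
    if n <= 16:
        if n >= 4:
            a = (_wyr4(data, 0) << 32) | _wyr4(data, (n >> 3) << 2)
            b = (_wyr4(data, n - 4) << 32) | _wyr4(data, n - 4 - ((n >> 3) << 2))
        elif n > 0:
            a = _wyr3(data, 0, n)
            b = 0
        else:
            a = b = 0
    else:
        i = n
        p = 0
        if i > 48:
            see1 = see2 = seed
            while i > 48:
                seed = _wymix(_wyr8(data, p) ^ _WYP[1], _wyr8(data, p + 8) ^ seed)
                see1 = _wymix(_wyr8(data, p + 16) ^ _WYP[2], _wyr8(data, p + 24) ^ see1)
                see2 = _wymix(_wyr8(data, p + 32) ^ _WYP[3], _wyr8(data, p + 40) ^ see2)
                p += 48
                i -= 48
            seed ^= see1 ^ see2
        while i > 16:
            seed = _wymix(_wyr8(data, p) ^ _WYP[1], _wyr8(data, p + 8) ^ seed)
            p += 16
            i -= 16
        a = _wyr8(data, p + i - 16)
        b = _wyr8(data, p + i - 8)
    return _wymix(_WYP[1] ^ n, _wymix(a ^ _WYP[1], b ^ seed))


# ---------------------------------------------------------------------------


def serialize_words(words: Iterable[int]) -> bytes:
    """Byte serialization fed to XX/WY: little-endian per word,
    words kept in most-significant-first order."""
    return b"".join(int(w).to_bytes(8, "little") for w in words)


def xor_fold(words: Iterable[int]) -> int:
    v = 0
    for w in words:
        v ^= int(w)
    return v


def strobe_hash(v: StrobeValue | int, scheme: HashScheme, l: int | None = None) -> int:
    """Hash one packed strobe value under ``scheme``.

    Accepts a :class:`StrobeValue` or a bare 64-bit integer (treated
    as a single-word value). NO is the identity on single-word input
    and an XOR fold across words otherwise.
    """
    scheme = HashScheme(scheme)
    if isinstance(v, StrobeValue):
        words: tuple[int, ...] = v.words
    else:
        words = (int(v) & _M64,)
    if scheme is HashScheme.NO:
        return xor_fold(words)
    if scheme is HashScheme.TW:
        if len(words) > 1:
            raise IncompatibleSchemeError(
                "TW hashes 64-bit integers only; strobes longer than 32 nt "
                f"need {len(words)} words"
            )
        return thomas_wang_64(words[0])
    data = serialize_words(words)
    if scheme is HashScheme.XX:
        return xxh64(data)
    return wyhash64(data)
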