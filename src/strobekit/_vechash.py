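"""Vectorized (numpy) batch versions of the strobe hash functions.

Inputs are ``(N, nw)`` uint64 arrays of packed l-mers (most significant
word first, as produced by :func:`strobekit.encoding.lmer_words`); the
hashed byte stream is the little-endian serialization of each row, so
results are bit-identical to the scalar functions in
:mod:`strobekit.hashing` applied row by row. Word counts are always
whole, i.e. input lengths are multiples of 8 bytes, which keeps every
lane read aligned on a word.
"""

from __future__ import annotations

import numpy as np

from .hashing import (
    _WYP,
    _XXP1,
    _XXP2,
    _XXP3,
    _XXP4,
    _XXP5,
    HashScheme,
    IncompatibleSchemeError,
)

__all__ = ["thomas_wang_vec", "xxh64_words", "wyhash_words", "hash_words"]

_U = np.uint64
_M32 = _U(0xFFFFFFFF)


def _rotl(x: np.ndarray, r: int) -> np.ndarray:
    return (x << _U(r)) | (x >> _U(64 - r))


def thomas_wang_vec(x: np.ndarray) -> np.ndarray:
    """Thomas Wang 64-bit mix applied elementwise."""
    x = np.asarray(x, dtype=np.uint64)
    x = ~x + (x << _U(21))
    x = x ^ (x >> _U(24))
    x = x + (x << _U(3)) + (x << _U(8))
    x = x ^ (x >> _U(14))
    x = x + (x << _U(2)) + (x << _U(4))
    x = x ^ (x >> _U(28))
    x = x + (x << _U(31))
    return x


# ---------------------------------------------------------------------------
# xxHash64


def _xx_round(acc: np.ndarray | int, lane: np.ndarray) -> np.ndarray:
    return _rotl(acc + lane * _U(_XXP2), 31) * _U(_XXP1)


def xxh64_words(words: np.ndarray, seed: int = 0) -> np.ndarray:
    """xxHash64 of each row's byte serialization."""
    words = np.atleast_2d(np.asarray(words, dtype=np.uint64))
    n_rows, nw = words.shape
    nbytes = 8 * nw
    p = 0
    if nbytes >= 32:
        a1 = np.full(n_rows, _U((seed + _XXP1 + _XXP2) & 0xFFFFFFFFFFFFFFFF))
        a2 = np.full(n_rows, _U((seed + _XXP2) & 0xFFFFFFFFFFFFFFFF))
        a3 = np.full(n_rows, _U(seed))
        a4 = np.full(n_rows, _U((seed - _XXP1) & 0xFFFFFFFFFFFFFFFF))
        while (p + 4) * 8 <= nbytes + p * 0 and p + 4 <= nw:
            a1 = _xx_round(a1, words[:, p])
            a2 = _xx_round(a2, words[:, p + 1])
            a3 = _xx_round(a3, words[:, p + 2])
            a4 = _xx_round(a4, words[:, p + 3])
            p += 4
        h = _rotl(a1, 1) + _rotl(a2, 7) + _rotl(a3, 12) + _rotl(a4, 18)
        for acc in (a1, a2, a3, a4):
            h = (h ^ _xx_round(0, acc)) * _U(_XXP1) + _U(_XXP4)
    else:
        h = np.full(n_rows, _U((seed + _XXP5) & 0xFFFFFFFFFFFFFFFF))
    h = h + _U(nbytes)
    while p < nw:
        h = h ^ _xx_round(0, words[:, p])
        h = _rotl(h, 27) * _U(_XXP1) + _U(_XXP4)
        p += 1
    h ^= h >> _U(33)
    h *= _U(_XXP2)
    h ^= h >> _U(29)
    h *= _U(_XXP3)
    h ^= h >> _U(32)
    return h


# ---------------------------------------------------------------------------
# wyhash (final_3 construction)


def _mum(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full 64x64 -> 128-bit product as (low, high) uint64 arrays."""
    ah = a >> _U(32)
    al = a & _M32
    bh = b >> _U(32)
    bl = b & _M32
    t = ah * bl + ((al * bl) >> _U(32))
    t2 = al * bh + (t & _M32)
    hi = ah * bh + (t >> _U(32)) + (t2 >> _U(32))
    return a * b, hi


def _wymix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lo, hi = _mum(np.asarray(a, dtype=np.uint64), np.asarray(b, dtype=np.uint64))
    return lo ^ hi


def wyhash_words(words: np.ndarray, seed: int = 0) -> np.ndarray:
    """wyhash (final_3) of each row's byte serialization."""
    words = np.atleast_2d(np.asarray(words, dtype=np.uint64))
    n_rows, nw = words.shape
    n = 8 * nw
    seedv = np.full(n_rows, _U(seed ^ _WYP[0]))
    if nw == 1:
        w0 = words[:, 0]
        a = ((w0 & _M32) << _U(32)) | (w0 >> _U(32))
        b = w0.copy()
    elif nw == 2:
        w0, w1 = words[:, 0], words[:, 1]
        a = ((w0 & _M32) << _U(32)) | (w1 & _M32)
        b = ((w1 >> _U(32)) << _U(32)) | (w0 >> _U(32))
    else:
        i = n
        p = 0  # word index; byte offset is 8*p
        if i > 48:
            see1 = seedv.copy()
            see2 = seedv.copy()
            while i > 48:
                seedv = _wymix(words[:, p] ^ _U(_WYP[1]), words[:, p + 1] ^ seedv)
                see1 = _wymix(words[:, p + 2] ^ _U(_WYP[2]), words[:, p + 3] ^ see1)
                see2 = _wymix(words[:, p + 4] ^ _U(_WYP[3]), words[:, p + 5] ^ see2)
                p += 6
                i -= 48
            seedv = seedv ^ see1 ^ see2
        while i > 16:
            seedv = _wymix(words[:, p] ^ _U(_WYP[1]), words[:, p + 1] ^ seedv)
            p += 2
            i -= 16
        a = words[:, (8 * p + i - 16) // 8]
        b = words[:, (8 * p + i - 8) // 8]
    return _wymix(_U(_WYP[1] ^ n), _wymix(a ^ _U(_WYP[1]), b ^ seedv))


# ---------------------------------------------------------------------------


def hash_words(words: np.ndarray, scheme: HashScheme | str) -> np.ndarray:
    """Hash each packed strobe row under ``scheme`` (batch strobe_hash).

    NO XOR-folds the words of each row; TW requires single-word rows.
    """
    scheme = HashScheme(scheme)
    words = np.atleast_2d(np.asarray(words, dtype=np.uint64))
    nw = words.shape[1]
    if scheme is HashScheme.NO:
        out = words[:, 0].copy()
        for k in range(1, nw):
            out ^= words[:, k]
        return out
    if scheme is HashScheme.TW:
        if nw > 1:
            raise IncompatibleSchemeError(
                "TW hashes 64-bit integers only; strobes longer than 32 nt "
                f"need {nw} words"
            )
        return thomas_wang_vec(words[:, 0])
    if scheme is HashScheme.XX:
        return xxh64_words(words)
    return wyhash_words(words)
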