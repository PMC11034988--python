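"""Randstrobe seed construction.

A randstrobe links ``n`` l-mers ("strobes"): strobe 0 is anchored at
the seed start ``i``; strobe ``k`` (k >= 1) is the candidate starting
in the window ``[i + w_min + (k-1)*w_max, i + k*w_max]`` (inclusive,
``W = w_max - w_min + 1`` candidates) that minimizes or maximizes a
link function of the current base value and the candidate. The base
is the strobe-0 hash for the first link and the running final hash of
the already-linked prefix afterwards. The final 64-bit seed hash is

    f(z0, z1)          = 2*z0 - z1            (n = 2)
    f(z0, ..., z_{n-1}) = 2*f(z0..z_{n-2}) - z_{n-1}   (n > 2)

over the per-strobe hash values, all arithmetic modulo 2**64.

Link functions (base b, candidate hash z', raw values x0/x1'):

    MOD   (b + z') mod p
    AND   (b + z') & q
    BC    popcount(b XOR z')
    XOR   b XOR z'
    XV    h(x0 XOR x1')           (expensive: rehash per candidate)
    CC    h(x0 || x1')            (expensive)
    MAMD  ((b mod p) + (z' mod p)) mod p

MAMD is arithmetically a modulo link whose window extremum can be
answered from an ordered multiset of residues in O(log W), which
:func:`build_randstrobes_mamd` exploits; :func:`build_randstrobes`
computes every link by linear window scan (vectorized over seed
starts) and is the reference for all links including MAMD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from ._vechash import hash_words
from .encoding import EncodedSequence, StrobeValue, lmer_words
from .hashing import HashScheme, IncompatibleSchemeError, strobe_hash
from .multiset import OpCounter, OrderedMultiset

__all__ = [
    "Link",
    "Comparator",
    "RandstrobeParams",
    "Randstrobe",
    "RandstrobeSet",
    "DEFAULT_P",
    "LARGE_WINDOW_P",
    "DEFAULT_Q",
    "final_hash",
    "link_value",
    "select_in_window",
    "build_randstrobes",
    "build_randstrobes_mamd",
    "kmer_seeds",
]

_M64 = (1 << 64) - 1
_U = np.uint64

#: Default modulus for MOD/MAMD and the large-window alternative.
DEFAULT_P = 100_001
LARGE_WINDOW_P = 19_019_684_767_739_993
#: Default AND bitmask: 16 ones on the least significant bits.
DEFAULT_Q = 0xFFFF

CHEAP_LINKS = frozenset({"MOD", "AND", "BC", "XOR", "MAMD"})
EXPENSIVE_LINKS = frozenset({"XV", "CC"})


class Link(str, enum.Enum):
    MOD = "MOD"
    AND = "AND"
    BC = "BC"
    XOR = "XOR"
    XV = "XV"
    CC = "CC"
    MAMD = "MAMD"

    @property
    def cheap(self) -> bool:
        """True if per-strobe hashing separates from linking."""
        return self.value in CHEAP_LINKS


class Comparator(str, enum.Enum):
    MIN = "MIN"
    MAX = "MAX"


@dataclass(frozen=True)
class RandstrobeParams:
    """Full parametrization of randstrobe construction.

    Defaults follow the standard benchmark setting
    ``(n=2, l=20, w_min=21, w_max=100)`` with the wyhash scheme.
    ``m`` is the neighbor depth of the conflict metric (defaults to
    ``w_max`` when unset: seeds farther apart than the window span
    cannot share selection bias from the same repeat instance).
    """

    n: int = 2
    l: int = 20
    w_min: int = 21
    w_max: int = 100
    hash_scheme: HashScheme = HashScheme.WY
    link: Link = Link.XOR
    comparator: Comparator = Comparator.MAX
    p: int = DEFAULT_P
    q: int = DEFAULT_Q
    m: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hash_scheme", HashScheme(self.hash_scheme))
        object.__setattr__(self, "link", Link(self.link))
        object.__setattr__(self, "comparator", Comparator(self.comparator))

    @property
    def window_size(self) -> int:
        """W, the number of candidate strobes per window."""
        return self.w_max - self.w_min + 1

    @property
    def conflict_depth(self) -> int:
        return self.w_max if self.m is None else self.m

    def validate(self) -> "RandstrobeParams":
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 1 <= self.l <= self.w_min <= self.w_max:
            raise ValueError("need 1 <= l <= w_min <= w_max")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.hash_scheme is HashScheme.TW and self.l > 32:
            raise IncompatibleSchemeError(
                f"TW with l={self.l}: strobes longer than 32 nt do not fit a "
                "64-bit integer"
            )
        if (
            self.link is Link.CC
            and self.hash_scheme is HashScheme.TW
            and 2 * (2 * self.l) > 64
        ):
            raise IncompatibleSchemeError(
                f"CC with TW requires the concatenation to fit 64 bits (l <= 16), got l={self.l}"
            )
        return self

    def with_(self, **kwargs) -> "RandstrobeParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Randstrobe:
    """One sampled seed: strobe start positions and the final hash."""

    positions: tuple[int, ...]
    hash: int

    @property
    def start(self) -> int:
        return self.positions[0]


class RandstrobeSet:
    """Column-oriented collection of randstrobes from one sequence.

    ``positions`` is an ``(N, n)`` int64 array of strobe starts (column
    0 is the seed start, rows sorted by it); ``hashes`` the matching
    uint64 final hashes. Indexing yields :class:`Randstrobe` records.
    """

    def __init__(
        self,
        positions: np.ndarray,
        hashes: np.ndarray,
        l: int,
        params: RandstrobeParams | None = None,
        stats: dict | None = None,
    ):
        positions = np.asarray(positions, dtype=np.int64)
        if positions.ndim == 1:
            positions = positions.reshape(len(hashes), -1)
        self.positions = positions
        self.hashes = np.asarray(hashes, dtype=np.uint64)
        self.l = int(l)
        self.params = params
        self.stats = stats or {}

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    @property
    def starts(self) -> np.ndarray:
        return self.positions[:, 0]

    def __len__(self) -> int:
        return int(self.hashes.size)

    def __getitem__(self, i: int) -> Randstrobe:
        return Randstrobe(tuple(int(x) for x in self.positions[i]), int(self.hashes[i]))

    def __iter__(self) -> Iterator[Randstrobe]:
        return (self[i] for i in range(len(self)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RandstrobeSet):
            return NotImplemented
        return (
            self.positions.shape == other.positions.shape
            and bool(np.array_equal(self.positions, other.positions))
            and bool(np.array_equal(self.hashes, other.hashes))
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start": self.starts,
                "positions": [",".join(map(str, row)) for row in self.positions],
                "hash": [f"{int(h):016x}" for h in self.hashes],
            }
        )


def final_hash(z: Sequence[int]) -> int:
    """Final seed hash f over per-strobe hash values, modulo 2**64."""
    if len(z) < 2:
        raise ValueError("final_hash needs at least 2 strobe hash values")
    acc = int(z[0])
    for zk in z[1:]:
        acc = (2 * acc - int(zk)) & _M64
    return acc


def _widen_raw(base: int, nw: int) -> StrobeValue | None:
    """Widen a 64-bit base value to an nw-word raw operand (low word)."""
    words = (0,) * (nw - 1) + (base & _M64,)
    # bypass StrobeValue width checks: construct equivalent container
    sv = object.__new__(StrobeValue)
    object.__setattr__(sv, "l", nw * 32)
    object.__setattr__(sv, "words", words)
    return sv


def _cc_words(base_raw: StrobeValue, cand_raw: StrobeValue, scheme: HashScheme, l: int):
    if scheme is HashScheme.TW:
        if 2 * (2 * l) > 64:
            raise IncompatibleSchemeError(
                f"CC with TW requires l <= 16, got l={l}"
            )
        packed = ((base_raw.value << (2 * l)) | cand_raw.value) & _M64
        return (packed,)
    return tuple(base_raw.words) + tuple(cand_raw.words)


def link_value(
    link: Link | str,
    base: int,
    cand_hash: int,
    cand_raw: StrobeValue | None = None,
    base_raw: StrobeValue | int | None = None,
    params: RandstrobeParams | None = None,
) -> int:
    """Scalar link function value for one (base, candidate) pair.

    ``base`` and ``cand_hash`` are 64-bit (hashed) values; XV/CC
    additionally require the raw packed encodings. All arithmetic is
    modulo 2**64.
    """
    link = Link(link)
    params = params or RandstrobeParams()
    base &= _M64
    cand_hash &= _M64
    if link is Link.MOD:
        return ((base + cand_hash) & _M64) % params.p
    if link is Link.AND:
        return ((base + cand_hash) & _M64) & params.q
    if link is Link.BC:
        return (base ^ cand_hash).bit_count()
    if link is Link.XOR:
        return base ^ cand_hash
    if link is Link.MAMD:
        return ((base % params.p) + (cand_hash % params.p)) % params.p
    # expensive links need raw material
    if cand_raw is None:
        raise ValueError(f"link {link.value} requires the candidate's raw encoding")
    if base_raw is None:
        raise ValueError(f"link {link.value} requires the base's raw operand")
    if isinstance(base_raw, int):
        base_raw = _widen_raw(base_raw, len(cand_raw.words))
    if link is Link.XV:
        mixed = tuple(a ^ b for a, b in zip(base_raw.words, cand_raw.words))
        sv = object.__new__(StrobeValue)
        object.__setattr__(sv, "l", cand_raw.l)
        object.__setattr__(sv, "words", mixed)
        return strobe_hash(sv, params.hash_scheme)
    # CC
    words = _cc_words(base_raw, cand_raw, params.hash_scheme, cand_raw.l)
    if params.hash_scheme is HashScheme.TW:
        return strobe_hash(words[0], params.hash_scheme)
    sv = object.__new__(StrobeValue)
    object.__setattr__(sv, "l", 32 * len(words))
    object.__setattr__(sv, "words", tuple(w & _M64 for w in words))
    return strobe_hash(sv, params.hash_scheme)


def select_in_window(values: Sequence[int], comparator: Comparator | str) -> int:
    """Index of the extreme link value; ties go to the lowest index."""
    if len(values) == 0:
        raise ValueError("empty candidate window")
    comparator = Comparator(comparator)
    pick = min if comparator is Comparator.MIN else max
    # both min() and max() return the lowest index among ties
    return int(pick(range(len(values)), key=lambda i: values[i]))


def _empty_set(params: RandstrobeParams) -> RandstrobeSet:
    return RandstrobeSet(
        np.empty((0, params.n), dtype=np.int64),
        np.empty(0, dtype=np.uint64),
        l=params.l,
        params=params,
    )


def _link_vec(
    link: Link,
    base: np.ndarray,
    cand_h: np.ndarray,
    params: RandstrobeParams,
    base_mod: np.ndarray | None = None,
    cand_mod: np.ndarray | None = None,
    base_raw: np.ndarray | None = None,
    cand_raw: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized link values for one window offset (uint64 array)."""
    if link is Link.MOD:
        return (base + cand_h) % _U(params.p)
    if link is Link.AND:
        return (base + cand_h) & _U(params.q)
    if link is Link.BC:
        return np.bitwise_count(base ^ cand_h).astype(np.uint64)
    if link is Link.XOR:
        return base ^ cand_h
    if link is Link.MAMD:
        return (base_mod + cand_mod) % _U(params.p)
    if link is Link.XV:
        return hash_words(base_raw ^ cand_raw, params.hash_scheme)
    # CC
    if params.hash_scheme is HashScheme.TW:
        packed = (base_raw[:, 0] << _U(2 * params.l)) | cand_raw[:, 0]
        return hash_words(packed[:, None], params.hash_scheme)
    return hash_words(np.concatenate([base_raw, cand_raw], axis=1), params.hash_scheme)


def build_randstrobes(
    seq: EncodedSequence,
    params: RandstrobeParams,
    chunk_size: int = 1 << 15,
) -> RandstrobeSet:
    """Construct all randstrobes of ``seq`` by linear window scan.

    One seed per start position ``i = 0 .. |S| - n*w_max - l``; empty
    set when the sequence is shorter than the reserved span. The scan
    is vectorized over seed starts (processed in chunks) but evaluates
    every one of the W candidates per window, for any link function.
    ``stats`` on the result records hash calls and link evaluations.
    """
    params.validate()
    n, l = params.n, params.l
    span = n * params.w_max + l
    num = seq.length - span + 1
    if num <= 0:
        return _empty_set(params)
    words = lmer_words(seq, l)
    H = hash_words(words, params.hash_scheme)
    nw = words.shape[1]
    expensive = not params.link.cheap
    Hmod = H % _U(params.p) if params.link is Link.MAMD else None

    positions = np.empty((num, n), dtype=np.int64)
    positions[:, 0] = np.arange(num)
    hashes = np.empty(num, dtype=np.uint64)
    link_evals = 0
    cmp_max = params.comparator is Comparator.MAX

    for s in range(0, num, chunk_size):
        e = min(s + chunk_size, num)
        m = e - s
        idx0 = np.arange(s, e)
        base = H[s:e].copy()  # z0; becomes running prefix final hash
        base_raw = words[s:e] if expensive else None
        for k in range(1, n):
            d0 = params.w_min + (k - 1) * params.w_max
            d1 = k * params.w_max
            if expensive and k > 1:
                base_raw = np.zeros((m, nw), dtype=np.uint64)
                base_raw[:, -1] = base
            base_mod = base % _U(params.p) if params.link is Link.MAMD else None
            best_val: np.ndarray | None = None
            best_off = np.empty(m, dtype=np.int64)
            for d in range(d0, d1 + 1):
                cand_h = H[s + d : s + d + m]
                lv = _link_vec(
                    params.link,
                    base,
                    cand_h,
                    params,
                    base_mod=base_mod,
                    cand_mod=Hmod[s + d : s + d + m] if Hmod is not None else None,
                    base_raw=base_raw,
                    cand_raw=words[s + d : s + d + m] if expensive else None,
                )
                link_evals += m
                if best_val is None:
                    best_val = lv
                    best_off[:] = d
                else:
                    better = lv > best_val if cmp_max else lv < best_val
                    best_val[better] = lv[better]
                    best_off[better] = d
            sel = idx0 + best_off
            positions[s:e, k] = sel
            base = _U(2) * base - H[sel]
        hashes[s:e] = base

    stats = {
        "hash_calls": int(H.size) if not expensive else int(H.size + link_evals),
        "link_evals": int(link_evals),
        "window_size": params.window_size,
    }
    return RandstrobeSet(positions, hashes, l=l, params=params, stats=stats)


def build_randstrobes_mamd(
    seq: EncodedSequence,
    params: RandstrobeParams,
    counter: OpCounter | None = None,
) -> RandstrobeSet:
    """MAMD construction via a sliding ordered multiset.

    Produces positions and hashes bit-identical to
    ``build_randstrobes`` with ``link=MAMD``, but answers each window
    selection with O(log W) ordered-multiset operations instead of a
    linear scan. The multiset per window order k holds ``(residue,
    position)`` pairs with residue = strobe hash mod p; for base
    residue ``a`` the linked value of candidate residue ``v`` is
    ``(a + v) mod p``, i.e. ``a + v - p`` when ``v >= p - a`` (wrap)
    and ``a + v`` otherwise, so the extremum is found by one
    successor/predecessor query at the wrap boundary ``p - a``.
    Ties on the residue resolve to the smallest position, matching
    the linear scan's leftmost tie-break.
    """
    params.validate()
    if params.link is not Link.MAMD:
        raise ValueError(f"build_randstrobes_mamd requires link=MAMD, got {params.link.value}")
    n, l, p = params.n, params.l, params.p
    span = n * params.w_max + l
    num = seq.length - span + 1
    if num <= 0:
        return _empty_set(params)
    words = lmer_words(seq, l)
    H = hash_words(words, params.hash_scheme).tolist()
    res = [h % p for h in H]
    counter = counter if counter is not None else OpCounter()
    cmp_max = params.comparator is Comparator.MAX

    windows = []
    for k in range(1, n):
        d0 = params.w_min + (k - 1) * params.w_max
        d1 = k * params.w_max
        ms = OrderedMultiset(counter)
        for pos in range(d0, d1 + 1):
            ms.add((res[pos], pos))
        windows.append((d0, d1, ms))

    positions = np.empty((num, n), dtype=np.int64)
    positions[:, 0] = np.arange(num)
    hashes = np.empty(num, dtype=np.uint64)

    for i in range(num):
        fh = H[i]
        for k in range(1, n):
            d0, d1, ms = windows[k - 1]
            a = fh % p
            t = p - a  # residues >= t wrap around the modulus
            if not cmp_max:
                chosen = ms.successor((t, -1))
                if chosen is None:
                    chosen = ms.min()
            else:
                pred = ms.predecessor((t, -1))
                vstar = pred[0] if pred is not None else ms.max()[0]
                chosen = ms.successor((vstar, -1))
            pos_k = chosen[1]
            positions[i, k] = pos_k
            fh = (2 * fh - H[pos_k]) & _M64
        hashes[i] = fh
        if i + 1 < num:
            for k in range(1, n):
                d0, d1, ms = windows[k - 1]
                ms.remove((res[i + d0], i + d0))
                ms.add((res[i + 1 + d1], i + 1 + d1))

    stats = {
        "multiset_ops": counter.ops,
        "multiset_comparisons": counter.comparisons,
        "window_size": params.window_size,
        "hash_calls": len(H),
    }
    return RandstrobeSet(positions, hashes, l=l, params=params, stats=stats)


def kmer_seeds(
    seq: EncodedSequence,
    k: int,
    hash_scheme: HashScheme | str = HashScheme.WY,
) -> RandstrobeSet:
    """k-mer reference seeds stored as two adjacent (k/2)-mer strobes.

    Each position yields the pair at ``(i, i + k/2)`` hashed with the
    scheme and combined with the same final hash ``2*z0 - z1`` as the
    randstrobes, making k-mers directly comparable in the benchmarks.
    """
    if k % 2:
        raise ValueError("k must be even (two equal strobes)")
    half = k // 2
    scheme = HashScheme(hash_scheme)
    if scheme is HashScheme.TW and half > 32:
        raise IncompatibleSchemeError(f"TW with {half}-nt strobes does not fit 64 bits")
    num = seq.length - k + 1
    if num <= 0:
        return RandstrobeSet(
            np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.uint64), l=half
        )
    words = lmer_words(seq, half)
    H = hash_words(words, scheme)
    z0 = H[:num]
    z1 = H[half : half + num]
    hashes = _U(2) * z0 - z1
    positions = np.empty((num, 2), dtype=np.int64)
    positions[:, 0] = np.arange(num)
    positions[:, 1] = positions[:, 0] + half
    return RandstrobeSet(positions, hashes, l=half)
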