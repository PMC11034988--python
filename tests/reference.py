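"""Independent brute-force oracles for the test suite.

Everything here is written as plainly as possible — character-level
l-mer extraction, explicit per-window linear scans with longhand link
formulas, double-loop metrics — and deliberately avoids the vectorized
code paths under test. Per-strobe hashing reuses the package's scalar
hash transcriptions, which are themselves pinned by published test
vectors in test_hashing.py.
"""

from __future__ import annotations

from collections import Counter

from strobekit.hashing import HashScheme, serialize_words, thomas_wang_64, wyhash64, xxh64

M64 = (1 << 64) - 1


def lmer_value(s: str, pos: int, l: int) -> int:
    """Arbitrary-precision 2-bit packed value of s[pos:pos+l]."""
    v = 0
    for ch in s[pos : pos + l]:
        v = (v << 2) | "ACGT".index(ch)
    return v


def value_to_words(v: int, l: int) -> list[int]:
    nw = (l + 31) // 32
    return [(v >> (64 * (nw - 1 - i))) & M64 for i in range(nw)]


def hash_value(v: int, l: int, scheme: str) -> int:
    words = value_to_words(v, l)
    if scheme == "NO":
        acc = 0
        for w in words:
            acc ^= w
        return acc
    if scheme == "TW":
        assert len(words) == 1
        return thomas_wang_64(words[0])
    data = serialize_words(words)
    return xxh64(data) if scheme == "XX" else wyhash64(data)


def hash_words_list(words: list[int], scheme: str) -> int:
    if scheme == "NO":
        acc = 0
        for w in words:
            acc ^= w
        return acc
    if scheme == "TW":
        assert len(words) == 1
        return thomas_wang_64(words[0])
    data = serialize_words(words)
    return xxh64(data) if scheme == "XX" else wyhash64(data)


def brute_build(s: str, params) -> list[tuple[tuple[int, ...], int]]:
    """Linear-scan randstrobe construction, one candidate at a time.

    Returns [(positions, final_hash), ...] in seed-start order.
    """
    n, l = params.n, params.l
    scheme = HashScheme(params.hash_scheme).value
    link = params.link.value
    cmp_max = params.comparator.value == "MAX"
    p, q = params.p, params.q
    nw = (l + 31) // 32
    num = len(s) - n * params.w_max - l + 1
    out = []
    for i in range(max(0, num)):
        x0 = lmer_value(s, i, l)
        base = hash_value(x0, l, scheme)  # z0; becomes running final hash
        base_raw_words = value_to_words(x0, l)
        positions = [i]
        for k in range(1, n):
            d0 = params.w_min + (k - 1) * params.w_max
            d1 = k * params.w_max
            best_val = None
            best_pos = None
            for d in range(d0, d1 + 1):
                x1 = lmer_value(s, i + d, l)
                z1 = hash_value(x1, l, scheme)
                if link == "MOD":
                    lv = ((base + z1) & M64) % p
                elif link == "AND":
                    lv = ((base + z1) & M64) & q
                elif link == "BC":
                    lv = bin((base ^ z1) & M64).count("1")
                elif link == "XOR":
                    lv = base ^ z1
                elif link == "MAMD":
                    lv = ((base % p) + (z1 % p)) % p
                elif link == "XV":
                    cw = value_to_words(x1, l)
                    mixed = [a ^ b for a, b in zip(base_raw_words, cw)]
                    lv = hash_words_list(mixed, scheme)
                elif link == "CC":
                    cw = value_to_words(x1, l)
                    if scheme == "TW":
                        packed = (
                            (base_raw_words[-1] << (2 * l)) | cw[-1]
                        ) & M64
                        lv = hash_words_list([packed], scheme)
                    else:
                        lv = hash_words_list(base_raw_words + cw, scheme)
                else:
                    raise AssertionError(link)
                if (
                    best_val is None
                    or (cmp_max and lv > best_val)
                    or (not cmp_max and lv < best_val)
                ):
                    best_val = lv
                    best_pos = i + d
            positions.append(best_pos)
            zk = hash_value(lmer_value(s, best_pos, l), l, scheme)
            base = (2 * base - zk) & M64
            base_raw_words = [0] * (nw - 1) + [base]
        out.append((tuple(positions), base))
    return out


def brute_ehits(keys) -> float:
    counts = Counter(keys)
    n = len(keys)
    return sum(c * c for c in counts.values()) / n


def brute_conflict(positions, l: int, m: int) -> float:
    """Double-loop conflict metric over position rows."""
    N = len(positions)
    total = 0.0
    for i in range(N):
        ci = 0
        for j in range(i + 1, min(N, i + m) + 1):
            if j >= N:
                break
            ov = sum(
                max(0, l - abs(positions[j][k] - positions[i][k]))
                for k in range(len(positions[i]))
            )
            ci = max(ci, ov)
        total += ci
    return total / N


def brute_collisions(positions, hashes) -> int:
    tuples = {tuple(p) for p in positions}
    return len(tuples) - len(set(hashes))
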