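"""Sampling-bias and repetitiveness metrics for randstrobe seeds.

All four metrics reduce to *E-hits*: given occurrence counts
``x_1..x_M`` of M distinct keys among N observations, E-hits is the
expected multiplicity of the key of an observation drawn uniformly,

    E[X] = sum_i (x_i / N) * x_i = (1/N) * sum_i x_i**2,

ranging from 1 (all keys distinct) to N (a single key). Keyed by the
final seed hash it gives Ef (seed repetitiveness incl. hash
collisions); keyed by the inter-strobe distance, Ed (distance
clumping); keyed by the absolute position of the k-th strobe, Ep
(positional hotspots). The conflict metric C captures correlated
selections among neighboring seeds: for seed i it is the largest
summed same-order strobe overlap with any of the next m seeds,
averaged over seeds.

Raw values depend on sequence length and window geometry, so reports
are normalized against a baseline built by selecting downstream
strobes uniformly at random in each window (an upper bound on
sampling uniformity that deliberately violates the determinism
required of a real seeding method); 1.0 then marks an ideal outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .construction import Randstrobe, RandstrobeParams, RandstrobeSet, _U
from ._vechash import hash_words
from .encoding import EncodedSequence, lmer_words

__all__ = [
    "CountTable",
    "MetricsReport",
    "ehits",
    "ef_metric",
    "ed_metric",
    "ep_metric",
    "conflict_metric",
    "collision_count",
    "compute_report",
    "random_baseline",
    "normalize_report",
]


@dataclass
class CountTable:
    """Multiset of occurrence counts x_i feeding the E-hits formula."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("all counts must be >= 1")

    @classmethod
    def from_keys(cls, keys: np.ndarray) -> "CountTable":
        """Tally an array of observed keys."""
        _, counts = np.unique(np.asarray(keys), return_counts=True)
        return cls(counts)

    @property
    def N(self) -> int:
        """Total observations."""
        return int(self.counts.sum())

    @property
    def M(self) -> int:
        """Distinct keys."""
        return int(self.counts.size)


def ehits(table: CountTable) -> float:
    """(sum x_i**2) / N — expected multiplicity of a uniform draw."""
    if table.M == 0:
        raise ValueError("E-hits of an empty count table is undefined")
    c = table.counts.astype(np.float64)
    return float((c * c).sum() / table.N)


def _as_set(seeds: RandstrobeSet | Sequence[Randstrobe]) -> RandstrobeSet:
    if isinstance(seeds, RandstrobeSet):
        return seeds
    seeds = list(seeds)
    if not seeds:
        raise ValueError("empty seed collection")
    pos = np.array([s.positions for s in seeds], dtype=np.int64)
    hashes = np.array([s.hash for s in seeds], dtype=np.uint64)
    return RandstrobeSet(pos, hashes, l=0)


def ef_metric(seeds: RandstrobeSet | Sequence[Randstrobe]) -> float:
    """E-hits of the final seed hash values."""
    s = _as_set(seeds)
    if len(s) == 0:
        raise ValueError("empty seed collection")
    return ehits(CountTable.from_keys(s.hashes))


def ed_metric(seeds: RandstrobeSet | Sequence[Randstrobe], k: int = 1) -> float:
    """E-hits of the distance between strobe 0 and strobe k."""
    s = _as_set(seeds)
    if len(s) == 0:
        raise ValueError("empty seed collection")
    if not 1 <= k < s.n:
        raise ValueError(f"strobe order k={k} out of range for n={s.n}")
    dist = s.positions[:, k] - s.positions[:, 0]
    return ehits(CountTable.from_keys(dist))


def ep_metric(seeds: RandstrobeSet | Sequence[Randstrobe], k: int = 1) -> float:
    """E-hits of the absolute position of strobe k."""
    s = _as_set(seeds)
    if len(s) == 0:
        raise ValueError("empty seed collection")
    if not 1 <= k < s.n:
        raise ValueError(f"strobe order k={k} out of range for n={s.n}")
    return ehits(CountTable.from_keys(s.positions[:, k]))


def conflict_metric(
    seeds: RandstrobeSet | Sequence[Randstrobe],
    m: int,
    l: int | None = None,
) -> float:
    """Mean over seeds of the largest overlap with the next m seeds.

    The overlap of seeds i and j sums, over strobe orders k, the
    positional overlap ``max(0, l - |p_jk - p_ik|)`` of their k-th
    strobes; strobes of different orders are never compared. Seeds
    must be sorted by start position. Seeds with no downstream
    neighbor contribute 0.
    """
    s = _as_set(seeds)
    if len(s) == 0:
        raise ValueError("empty seed collection")
    if m < 1:
        raise ValueError("neighbor depth m must be >= 1")
    l = s.l if l is None else l
    if l < 1:
        raise ValueError("strobe length l must be given when seeds carry none")
    starts = s.positions[:, 0]
    if np.any(np.diff(starts) < 0):
        raise ValueError("seeds must be sorted by start position")
    N = len(s)
    P = s.positions
    ci = np.zeros(N, dtype=np.int64)
    for dj in range(1, min(m, N - 1) + 1):
        ov = np.zeros(N - dj, dtype=np.int64)
        for k in range(s.n):
            gap = np.abs(P[dj:, k] - P[:-dj, k])
            ov += np.clip(l - gap, 0, None)
        np.maximum(ci[: N - dj], ov, out=ci[: N - dj])
    return float(ci.mean())


def collision_count(seeds: RandstrobeSet | Sequence[Randstrobe]) -> int:
    """Distinct strobe-position tuples minus distinct final hashes.

    0 means the final hash is injective on the sampled tuples.
    """
    s = _as_set(seeds)
    if len(s) == 0:
        raise ValueError("empty seed collection")
    tuples = np.unique(
        np.ascontiguousarray(s.positions).view(
            np.dtype((np.void, s.positions.dtype.itemsize * s.n))
        )
    ).size
    hashes = np.unique(s.hashes).size
    return int(tuples - hashes)


@dataclass
class MetricsReport:
    """Raw bias metrics of one seed set, plus optional normalization."""

    ef: float
    ed: float
    ep: float
    conflict: float
    collisions: int
    meta: dict = field(default_factory=dict)
    normalized: dict | None = None


def compute_report(
    seeds: RandstrobeSet | Sequence[Randstrobe],
    m: int | None = None,
    l: int | None = None,
    k: int = 1,
) -> MetricsReport:
    """All metrics of one seed set (conflict depth m defaults to w_max)."""
    s = _as_set(seeds)
    if m is None:
        if s.params is None:
            raise ValueError("conflict depth m required when seeds carry no params")
        m = s.params.conflict_depth
    return MetricsReport(
        ef=ef_metric(s),
        ed=ed_metric(s, k),
        ep=ep_metric(s, k),
        conflict=conflict_metric(s, m, l),
        collisions=collision_count(s),
        meta={"n_seeds": len(s), "m": m, "k": k},
    )


def random_baseline(
    seq: EncodedSequence,
    params: RandstrobeParams,
    rng_seed: int = 0,
) -> MetricsReport:
    """Metrics of seeds whose downstream strobes are drawn uniformly
    at random in their windows (the near-ideal normalization target).

    Reproducible for a fixed ``rng_seed``; strobe hashes and the final
    hash use the scheme in ``params`` so Ef is comparable.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    num = seq.length - params.n * params.w_max - params.l + 1
    if num <= 0:
        raise ValueError("sequence too short for the given parameters")
    words = lmer_words(seq, params.l)
    H = hash_words(words, params.hash_scheme)
    positions = np.empty((num, params.n), dtype=np.int64)
    positions[:, 0] = np.arange(num)
    fh = H[:num].copy()
    for k in range(1, params.n):
        d0 = params.w_min + (k - 1) * params.w_max
        d1 = k * params.w_max
        sel = positions[:, 0] + rng.integers(d0, d1 + 1, size=num)
        positions[:, k] = sel
        fh = _U(2) * fh - H[sel]
    seeds = RandstrobeSet(positions, fh, l=params.l, params=params)
    rep = compute_report(seeds, m=params.conflict_depth)
    rep.meta["rng_seed"] = rng_seed
    rep.meta["baseline"] = True
    return rep


def normalize_report(report: MetricsReport, baseline: MetricsReport) -> MetricsReport:
    """Divide each metric by its baseline value; 1.0 = ideal sampling."""
    fields = ("ef", "ed", "ep", "conflict")
    for name in fields:
        if getattr(baseline, name) <= 0:
            raise ValueError(f"baseline {name} must be positive to normalize")
    return MetricsReport(
        ef=report.ef,
        ed=report.ed,
        ep=report.ep,
        conflict=report.conflict,
        collisions=report.collisions,
        meta=dict(report.meta, baseline_meta=baseline.meta),
        normalized={name: getattr(report, name) / getattr(baseline, name) for name in fields},
    )
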