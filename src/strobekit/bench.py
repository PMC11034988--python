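"""Method-combination benchmark: build seeds for every requested
(hash, link, comparator) combination, score the four bias metrics,
and normalize by the uniform-random baseline.

The output is a tidy table — one row per combination and metric —
plus the raw operation counts (hash calls, link evaluations) so that
construction cost can be compared hardware-independently. A k-mer
reference (k = 2l, stored as two half-k strobes with the same final
hash) is included so seed repetitiveness (Ef) can be judged against
plain k-mers covering the same number of positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .construction import (
    Comparator,
    Link,
    RandstrobeParams,
    build_randstrobes,
    build_randstrobes_mamd,
    kmer_seeds,
)
from .encoding import EncodedSequence, clean_sequence, encode
from .hashing import HashScheme, IncompatibleSchemeError
from .metrics import compute_report, ef_metric, normalize_report, random_baseline
from .simulate import RepeatSimParams, simulate_repetitive

__all__ = ["BenchConfig", "BenchResult", "combination_error", "all_combinations", "run_benchmark"]

Combo = tuple[HashScheme, Link, Comparator]


def combination_error(
    hash_scheme: HashScheme | str, link: Link | str, l: int
) -> str | None:
    """Why a (hash, link) pair is unusable at strobe length l, or None."""
    try:
        RandstrobeParams(l=l, w_min=max(l, 21), w_max=max(l, 21) + 79,
                         hash_scheme=hash_scheme, link=link).validate()
    except IncompatibleSchemeError as exc:
        return str(exc)
    return None


def all_combinations(l: int) -> tuple[list[Combo], list[tuple[Combo, str]]]:
    """All compatible (hash, link, comparator) combos at strobe length l,
    plus the excluded ones with reasons."""
    ok: list[Combo] = []
    excluded: list[tuple[Combo, str]] = []
    for h in HashScheme:
        for lk in Link:
            reason = combination_error(h, lk, l)
            for c in Comparator:
                if reason is None:
                    ok.append((h, lk, c))
                else:
                    excluded.append(((h, lk, c), reason))
    return ok, excluded


@dataclass
class BenchConfig:
    """Benchmark specification.

    ``sequence`` is a raw nucleotide string; alternatively ``sim``
    generates the repetitive stand-in. ``combos`` is an explicit list
    of (hash, link, comparator) triples or "all" for every compatible
    combination at the configured strobe length.
    """

    sequence: str | None = None
    sim: RepeatSimParams | None = field(default_factory=RepeatSimParams)
    combos: list[Combo] | str = "all"
    params: RandstrobeParams = field(default_factory=RandstrobeParams)
    baseline_seed: int = 0
    kmer_reference: bool = True

    def resolve_sequence(self) -> EncodedSequence:
        if self.sequence is not None:
            return encode(clean_sequence(self.sequence), "bench")
        if self.sim is None:
            raise ValueError("BenchConfig needs a sequence or simulator params")
        return encode(simulate_repetitive(self.sim), "sim")


@dataclass
class BenchResult:
    table: pd.DataFrame
    excluded: list[tuple[Combo, str]]


def run_benchmark(cfg: BenchConfig) -> BenchResult:
    """Run every combination and emit the tidy metric table.

    Explicitly requested incompatible combinations raise
    :class:`IncompatibleSchemeError` naming the pair; with
    ``combos="all"`` they are silently excluded and reported in the
    result instead.
    """
    seq = cfg.resolve_sequence()
    base = cfg.params
    if cfg.combos == "all":
        combos, excluded = all_combinations(base.l)
    else:
        combos = []
        excluded = []
        for h, lk, c in cfg.combos:
            reason = combination_error(h, lk, base.l)
            if reason is not None:
                raise IncompatibleSchemeError(
                    f"requested combination ({HashScheme(h).value}, {Link(lk).value}) "
                    f"is incompatible: {reason}"
                )
            combos.append((HashScheme(h), Link(lk), Comparator(c)))

    # one uniform-random baseline per hash scheme (positions are shared
    # because the rng seed is shared; Ef depends on the scheme)
    baselines = {}
    rows = []
    for h, lk, c in combos:
        params = base.with_(hash_scheme=h, link=lk, comparator=c).validate()
        if h not in baselines:
            baselines[h] = random_baseline(seq, params.with_(link=Link.MOD), cfg.baseline_seed)
        builder = build_randstrobes_mamd if lk is Link.MAMD else build_randstrobes
        seeds = builder(seq, params)
        report = normalize_report(compute_report(seeds), baselines[h])
        for metric in ("ef", "ed", "ep", "conflict"):
            rows.append(
                {
                    "hash": h.value,
                    "link": lk.value,
                    "comparator": c.value,
                    "metric": metric,
                    "raw": getattr(report, metric),
                    "baseline": getattr(baselines[h], metric),
                    "normalized": report.normalized[metric],
                    "collisions": report.collisions,
                    "n_seeds": report.meta["n_seeds"],
                    "hash_calls": seeds.stats.get("hash_calls"),
                    "link_evals": seeds.stats.get(
                        "link_evals", seeds.stats.get("multiset_ops")
                    ),
                }
            )

    if cfg.kmer_reference:
        for h in sorted({h for h, _, _ in combos}, key=lambda s: s.value):
            if h is HashScheme.TW and base.l > 32:
                continue
            seeds = kmer_seeds(seq, 2 * base.l, h)
            rows.append(
                {
                    "hash": h.value,
                    "link": "KMER",
                    "comparator": "-",
                    "metric": "ef",
                    "raw": ef_metric(seeds),
                    "baseline": float("nan"),
                    "normalized": float("nan"),
                    "collisions": None,
                    "n_seeds": len(seeds),
                    "hash_calls": None,
                    "link_evals": None,
                }
            )

    table = pd.DataFrame(rows)
    return BenchResult(table=table, excluded=excluded)
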