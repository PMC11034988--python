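"""Synthetic test sequences.

Two generators cover the regimes that matter for seed-sampling bias:
i.i.d. uniform sequences (the easy case — high entropy is nearly
free) and a highly repetitive tandem-like sequence that emulates
repeat-rich genomic regions: many copies of one unit, each copy
independently mutated by substitutions, embedded in random flanks.
Because copies recur at a fixed period, identical or near-identical
strobes reappear at recurring distances — exactly the situation in
which biased link/comparator combinations produce distance clumping
and seed collapse.

Defaults for the repetitive generator: 60 nt unit, 200 copies, 5%
per-base substitution rate (forced change to one of the three other
bases), 10 kb flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RepeatSimParams", "simulate_random", "simulate_repetitive"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode()


def simulate_random(length: int, rng_seed: int = 0) -> str:
    """i.i.d. uniform ACGT string of the given length."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(rng_seed)
    return _to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


@dataclass(frozen=True)
class RepeatSimParams:
    """Parameters of the tandem-like repetitive sequence generator."""

    unit_length: int = 60
    copies: int = 200
    sub_rate: float = 0.05
    flank_length: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must be in [0, 1]")
        if self.unit_length < 1 or self.flank_length < 0:
            raise ValueError("invalid lengths")


def simulate_repetitive(params: RepeatSimParams) -> str:
    """flank + copies of one random unit (each independently
    substituted at ``sub_rate``) + flank.

    A substitution always changes the base (uniform over the three
    alternatives), so ``sub_rate=0`` gives exact tandem copies and
    ``sub_rate=1`` leaves no position unchanged.
    """
    rng = np.random.default_rng(params.rng_seed)
    unit = rng.integers(0, 4, size=params.unit_length, dtype=np.uint8)
    tract = np.tile(unit, params.copies)
    mask = rng.random(size=tract.size) < params.sub_rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    tract[mask] = (tract[mask] + shift) % 4
    left = rng.integers(0, 4, size=params.flank_length, dtype=np.uint8)
    right = rng.integers(0, 4, size=params.flank_length, dtype=np.uint8)
    return _to_str(np.concatenate([left, tract, right]))
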