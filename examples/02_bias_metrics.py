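"""Measure sampling bias of operator combinations on a repetitive sequence.

Generates the tandem-repeat stand-in (60 nt unit x 200 copies, 5%
substitutions, 10 kb flanks), builds randstrobes for a few informative
hash/link/comparator combinations, and prints the bias metrics
normalized by a uniform-random selection baseline (1.0 = ideal):

  Ed  E-hits of the strobe-0 -> strobe-1 distance (distance clumping;
      the XOR+cmin collapse onto the 60 nt repeat period shows up here)
  Ep  E-hits of the absolute second-strobe position (hotspots)
  C   mean max overlap with the next w_max seeds (correlated choices)
  Ef  E-hits of the final hash (seed repetitiveness)
"""

from strobekit import (
    BenchConfig,
    RandstrobeParams,
    RepeatSimParams,
    run_benchmark,
)

cfg = BenchConfig(
    sim=RepeatSimParams(),  # the repetitive stand-in, rng_seed=0
    combos=[
        ("NO", "XOR", "MIN"),   # unhashed + collapse-prone
        ("WY", "XOR", "MIN"),   # hashed, still collapses on exact repeats
        ("WY", "XOR", "MAX"),   # hashed, collapse-free
        ("NO", "AND", "MAX"),   # unhashed masked sum
        ("WY", "AND", "MAX"),
        ("WY", "CC", "MAX"),    # expensive: rehash per candidate
    ],
    params=RandstrobeParams(),
    baseline_seed=0,
)
result = run_benchmark(cfg)

wide = result.table[result.table.link != "KMER"].pivot_table(
    index=["hash", "link", "comparator"], columns="metric", values="normalized"
)[["ed", "ep", "conflict", "ef"]]
print("normalized metrics (1.0 = uniform-random baseline):")
print(wide.round(3).to_string())

kmers = result.table[result.table.link == "KMER"]
print("\nraw Ef of plain 40-mers for comparison:")
print(kmers[["hash", "raw"]].round(3).to_string(index=False))
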