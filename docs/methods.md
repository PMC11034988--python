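# Methods

## The construction model

A randstrobe over a DNA string S (alphabet {A,C,G,T}, 2-bit encoded
A=00, C=01, G=10, T=11; other letters are removed before encoding, so
all coordinates refer to the cleaned sequence) is a seed of n l-mers
("strobes"). Strobe 0 starts at the seed start i; strobe k (k ≥ 1) is
chosen among the W = w_max − w_min + 1 candidates starting in
[i + w_min + (k−1)·w_max, i + k·w_max] (0-based, both ends inclusive).
The candidate that minimizes (cmin) or maximizes (cmax) a link
function ℓ(b, x′) of the current base value b and the candidate x′ is
selected; ties go to the leftmost candidate, a convention chosen
because it is position-stable and implementable identically in the
linear scan and the ordered-multiset constructor via (value, position)
ordering. One seed is produced per start position
i = 0 … |S| − n·w_max − l, so a string shorter than n·w_max + l yields
none. The seed is represented by the final hash

    f(z0, z1) = 2·z0 − z1,    f(z0,…,z_{n−1}) = 2·f(z0,…,z_{n−2}) − z_{n−1},

over the per-strobe hash values z_k = h(x_k), all arithmetic modulo
2^64. f is asymmetric (direction-preserving) and uncorrelated with
every benchmarked link function. The base value b is z0 for the first
link and the running prefix final hash afterwards; for the two links
that consume raw encodings (XV, CC) the base operand beyond the first
link is the 64-bit base value widened to the strobe word width (the
recursion has no natural raw operand; this keeps the interface total
and is configurable in principle).

### Hash schemes

* `NO` — the raw 2-bit encoding (multi-word values XOR-fold to one
  word so the scheme stays total; the fold is only exercised for
  l > 32, a combination the benchmarks flag as biased anyway).
* `TW` — Thomas Wang's invertible 64-bit mix; single-word only.
* `XX` — xxHash64 (seed 0) of the little-endian serialization of the
  packed words, most significant word first.
* `WY` — wyhash, pinned to the final_3 construction (secret constants
  0xa0761d6478bd642f, 0xe7037ed1a0b428db, 0x8ebc6af09c88c6e3,
  0x589965cc75374cc3; seed 0), same serialization.

xxHash64 and wyhash are implemented natively (scalar transcription +
numpy batch path, cross-checked bit-for-bit against each other and
against published test vectors in the suite). Strobe values longer
than 32 nt occupy ceil(l/32) 64-bit words, first base in the most
significant occupied bit pair, so numeric order equals lexicographic
order.

### Link functions

| link | value | class |
|------|-------|-------|
| MOD  | (b + z′) mod p | cheap |
| AND  | (b + z′) & q | cheap |
| BC   | popcount(b ⊕ z′) | cheap |
| XOR  | b ⊕ z′ | cheap |
| MAMD | ((b mod p) + (z′ mod p)) mod p | cheap, BST-accelerable |
| XV   | h(x0 ⊕ x′) | expensive |
| CC   | h(x0 ‖ x′) | expensive |

Cheap links hash each position once and combine hashes; expensive
links rehash every (base, candidate) pair. CC concatenates the fixed-
width word arrays; under TW (which only accepts one word) it instead
bit-packs (x0 << 2l) | x′, which is why CC+TW requires l ≤ 16. The
sums in MOD/AND wrap modulo 2^64 before the mask/modulus, matching
64-bit integer arithmetic in production implementations.

Defaults: p = 100 001 (19 019 684 767 739 993 for the large-window
regime — p must be far larger than W but smaller than the hash range;
beyond that its value is immaterial), q = 0xFFFF (16 low ones).

### The ordered-multiset (MAMD) constructor

For a fixed base residue a = b mod p, the linked value of a candidate
residue v is (a + v) mod p = a + v − p when v ≥ p − a and a + v
otherwise. Keeping the window's (v, position) pairs in an ordered
multiset, the cmin winner is the successor of (p − a, −∞) if one
exists (smallest wrapped value) and otherwise the multiset minimum;
cmax takes the predecessor's residue (largest unwrapped value),
falling back to the maximum residue, with one extra successor query to
return the smallest position among ties. Sliding the window is one
insert and one delete. The multiset is a sorted array with counted
binary search: every query costs O(log W) key comparisons (the
element moves are memmoves that a balanced tree would also avoid, but
they perform no comparisons and do not affect any reported count or
result). The constructor is bit-identical to the linear scan by
construction and by test.

MOD and MAMD are *not* interchangeable per window: the 64-bit wrap in
MOD's b + z′ occurs for roughly half of all pairs and shifts the value
by 2^64 mod p, so the argmin usually differs. Their bias metrics are
statistically indistinguishable for Ed and C; Ep is mildly but
systematically higher for MAMD because a candidate with an extremal
residue keeps winning consecutive windows, while MOD's wrap
rescrambles values every window.

## Bias metrics

All metrics reduce to E-hits of a count table {x_i}:
E[X] = (1/N) Σ x_i², the expected multiplicity of a uniformly drawn
observation, in [1, N]. Keys: final hash (Ef), distance
positions[k] − positions[0] (Ed), absolute position of strobe k (Ep).
The conflict metric C averages, over seeds, the largest summed
same-order strobe overlap max(0, l − |p_jk − p_ik|) with any of the
next m seeds; m defaults to w_max because more distant seeds cannot
share window-selection bias from the same repeat instance. Strobes of
different orders are never compared (their overlaps can occur for
legitimate geometric reasons). Seeds near the end of the sequence
with no downstream neighbor contribute 0.

Raw values depend on |S| and geometry, so reports are normalized by a
baseline that picks each downstream strobe uniformly at random in its
window (seeded, reproducible). The baseline deliberately violates the
determinism a real seeding method needs — it is an upper bound on
uniformity, not a usable sampler. Normalized 1.0 = ideal; Ep can drop
below 1 for methods that spread positions *more* evenly than uniform
sampling (anti-clumping, itself a bias).

Collision counting reports (distinct strobe-position tuples) −
(distinct final hashes); 0 means f is injective on the sample. The
birthday expectation for 64-bit hashes is ≈ N²/2^65, i.e. ~10⁻⁴
expected collisions at N = 10⁵.

## Synthetic data

`simulate_random` draws i.i.d. uniform bases. `simulate_repetitive`
emulates repeat-rich regions: one random unit, `copies` tandem
repetitions, each position substituted with probability `sub_rate`
(always to a different base), flanked by i.i.d. sequence. Defaults
(60 nt × 200 copies, 5% substitutions, 10 kb flanks) model a diverged
tandem array inside unique sequence; the recurring 60 nt period is
what XOR+cmin collapses onto. The generator does not model indels,
nested/interspersed repeat families, GC skew, or the length
distribution of real satellite arrays — passing tests demonstrate the
operator-level selection behavior, not performance on any particular
genome.

For the large-window analyses (128-nt strobes) the repeat identity is
set to 99.8% (sub_rate 0.002, 500 nt units): satellite-like arrays in
real assemblies are this homogeneous, and at 5% divergence no 128-mer
survives mutation, which would make every method trivially
collision-free and the comparison vacuous.

## Problem sizes and numerical choices

* Benchmarks and acceptance checks run at desk scale: the repetitive
  stand-in is ~32 kb, the collision check uses 10⁵ seeds, the
  large-window comparison a 1 Mb genome (0.5 Mb in the acceptance
  script), window-cost scaling a 0.2 Mb string with W up to 9 872.
  All quantities are ratios, rates, or per-seed counts and are stable
  at these sizes; construction cost is reported as operation counts
  (hash calls, link evaluations, multiset comparisons), which are
  hardware-independent, rather than wall-clock time.
* All unsigned arithmetic wraps modulo 2^64, including the subtraction
  in f. Link values are compared as unsigned integers.
* Comparator ties break to the leftmost candidate everywhere.
* Sequences shorter than the reserved span n·w_max + l yield an empty
  seed set rather than truncated windows, keeping the count formula
  exact.
* The "hashing matters" checks use cmax: under cmin the XOR collapse
  (identical strobes link to 0 and win) affects hashed and unhashed
  selection alike and masks the hashing effect being measured.

## Known limitations

* Reverse-complement/canonical seeds, syncmer thinning, FASTQ input
  and mapping-index construction are out of scope.
* wyhash bit-compatibility with the upstream C implementation is
  asserted against the final_3 test-vector table; other wyhash
  versions (final_4, condom modes) differ and are not provided.
* The BST constructor is implemented for the MAMD link only; its
  technique relies on modulo arithmetic and does not transfer to the
  other links.
* Entropy of the conditional sampling distribution is not computed
  directly; the four metrics are its operational proxies.
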