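# Methods

## Word counts and the background model

Sequences are uppercased on input; residues outside {A, C, G, T} are kept
in place but every k-window touching one is skipped and the window count
n_positions is reduced accordingly, so count vectors remain well defined on
real FASTA with ambiguity codes. Words are ranked by base-4 encoding with
the alphabetical digit assignment A=0, C=1, G=2, T=3; counts live in a
dense vector of length 4^k, capped at k = 12 as a memory guard
(4^12 ≈ 1.7·10^7 entries).

The background model is order-0 (i.i.d.): per-sequence mononucleotide
frequencies (or the exact uniform ¼ vector), with word probabilities taken
as products of letter probabilities. Centering is X̄_w = X_w −
n_positions·p_w. Higher-order Markov backgrounds are out of scope.

A consequence worth knowing: at k = 1 with an empirical background the
centered vector is identically zero, so the centered dissimilarities are
undefined there by construction; the package raises rather than returning
a conventional value. Use k ≥ 2 for d2S/d2* or the uniform background.

## Statistics and dissimilarities

D2 is the raw inner product; D2S normalises each word term by
√(X̄_w² + Ȳ_w²); D2\* by the Poisson-approximate standard deviations
√((n−k+1)p^X_w·(m−k+1)p^Y_w). Word terms whose denominator vanishes
contribute 0 — the limit of the summand — which also covers words with
zero background probability under degenerate compositions.

Each dissimilarity is d = ½(1 − S/√(S_xx·S_yy)) with the matching
self-normalisation sums (for d2S: S_xx = Σ X̄_w²/√(X̄_w²+Ȳ_w²), and
analogously with Poisson denominators for d2\*). By the weighted
Cauchy-Schwarz inequality the normalised statistic lies in [−1, 1], hence
d ∈ [0, 1], and d(x, x) = 0 exactly. For nonnegative raw counts the d2
cosine is nonnegative, so d2 ∈ [0, ½]. Frequency distances (Euclidean,
Manhattan, Chebyshev) divide counts by n−k+1 — the number of windows — so
frequencies sum to 1 for every k; this differs from dividing by the
sequence length n (identical only at k = 1) and is the deliberate choice
here because it keeps the vectors on the simplex.

Default k is 6; values of 4-6 are the usual compromise between resolution
and sparsity for genomic sequences.

## The block-cut T_sum statistic

Cutting starts at the 5′ end with a Q-block, then a W-spacer, repeated;
blocks sit at [iT, iT+Q) for T = Q+W, and a trailing partial block is
discarded rather than padded (padding would bias counts). Coverage is
r = Q/T; sweeps over r hold T fixed and set Q = round(rT).

The per-block scores are the row and column maxima of the N_x×N_y
cross-statistic matrix between the two block sets; the two block counts
need not be equal. The statistic inside the matrix defaults to D2S
computed on block-local counts, each block centered against its own
empirical background; D2 and D2\* are selectable. T_sum is the product of
the two per-block score sums, symmetric under exchanging the sequences.

## The simulators

Null pairs are two independent i.i.d. uniform sequences. Foreground pairs
implant a module: one random L-mer is drawn per replicate, candidate sites
are the non-overlapping grid positions 0, L, 2L, …, each selected
independently with probability `implant_prob` (default 0.05), and both
sequences are overwritten with the module at every selected site. The grid
keeps implants non-overlapping and makes the implant count Binomial,
which the tests exploit analytically. Identical placement in both
sequences is the strongest-signal reading of a shared-fragment foreground
and gives a cleanly tunable signal.

What this emulates: a pair of unrelated sequences sharing scattered exact
repeats of a common motif. What it does not emulate: genomic base
composition bias, Markov structure, mutated or indel-bearing module
copies, and position-shifted implants. Passing tests therefore demonstrate
the machinery's behaviour under exactly specified conditions, not
performance on real genomes.

Because the same module recurs at every implanted site, the signal in
count space is concentrated on the few words containing the module. This
has a scaling consequence worth stating explicitly: at larger k the null
count vectors are sparser, so a recurring module stands out *more*, and
measured power tends to *increase* with k (and mildly with L and with
fragmentation) under this generator. Studies on real recombined genomic
data report the opposite directions for k, L and the cutting period T;
those directions evidently depend on signal structure this generator does
not reproduce (independent, composition-matched shared fragments embedded
in non-uniform backgrounds). Two alternative foreground designs were
evaluated — per-site independent shared fragments, and a normalised
(cosine-form) block statistic — and neither restores those directions
while both weaken absolute power, so the shared-module design was kept.
The trend in coverage r is robust in all designs: more statistical
coverage, more power.

## Calibration and power

The significance threshold t is the empirical 95th percentile (higher
interpolation, so t is an attained order statistic) of T_sum over
simulated background-only pairs with the same length, scheme and k; a
configuration fingerprint guards against mixing a null calibration with a
mismatched power run. Power is the fraction of foreground replicates with
T_sum ≥ t. Defaults are 1000 null and 1000 foreground replicates; the
headline runs in `scripts/acceptance.py` use 500 + 500 per condition,
which gives a Monte-Carlo standard error on power of at most
√(0.25/500) ≈ 0.022 while keeping a full four-condition run under ten
seconds. Every replicate draws from a generator spawned off one master
seed (per-point seeds are master+index), so whole tables are reproducible
from a single integer.

Under a null foreground the test's size is ≈ 0.05; the test-suite band
[0.02, 0.08] at 1000+1000 replicates covers both the binomial spread and
the sampling error of the estimated threshold.

## Numerical and degenerate-input choices

- Zero-denominator word terms contribute 0 in D2S/D2\*; a fully zero
  normalisation sum (e.g. a sequence with no countable windows) raises an
  undefined-dissimilarity error instead of producing NaN.
- Ties at the threshold count as significant (≥, matching the attained
  order statistic).
- Coordinates are 0-based half-open everywhere, including implant-site
  records and block intervals.
- PHYLIP output uses the strict square dialect with 10-character labels;
  a TSV writer preserves full labels when truncation would collide.

## Known limitations

- The i.i.d. uniform background is the analysis model and the simulation
  truth here; on strongly skewed real genomes the empirical-background
  centering mitigates but does not remove composition effects.
- Power values depend on every generator setting; they are comparable
  across conditions within this package, not directly against numbers
  obtained from other data-generating processes (see the scaling note
  above).
- No reverse-complement collapsing: strand-asymmetric counting is
  intentional and matches the statistic definitions used.
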