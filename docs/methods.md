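# Methods

This note records the algorithms and statistical conventions implemented
in `wpal`, in enough detail to reproduce every number the package emits.

## Coordinates

Internally all intervals are 0-based half-open. Reported palindrome
tables are 1-based inclusive, so printed sizes obey
`size = end − start + 1`.

## Sexed-coverage identification of W-linked sequence

Inputs are interval depths from pooled-by-sex genotyping (hundreds of
offspring per pool) and deep resequencing of one individual per sex.
For each interval the classifier computes

* rule 1: `log2((M_pool + 1) / (F_pool + 1))`, required to fall below a
  bound `L`. `L` defaults to the 5th percentile of the rule-1
  distribution divided by the number of intervals tested; the divisor can
  be disabled (`l_divisor="one"`) or the bound fixed outright
  (`fixed_l`).
* rule 2: `log2((F_reseq + 1) / (M_reseq + 1)) > 5`, i.e. a more than
  32-fold female excess in the resequencing depths.

A contig with ≥ 3 female-specific markers is a candidate W contig.
Windowed male median depth (lower median; deterministic for even
windows) at ≤ 10× marks W-specific regions; contiguous same-label
windows merge into intervals. Hemizygous presence/absence markers
segregating `+/− × −/−` recode to `AB × BB` genotypes.

## Palindrome detection

1. **Seeding.** Every k-mer sampled each `step` bp (defaults k = 100,
   step = 20) is matched exactly against the reverse complement of every
   k-mer in the sequence; overlapping footprints are excluded. The seed
   set equals a brute-force scan (verified property).
2. **Chaining.** An inverted pair's two sides satisfy
   `plus + minus ≈ constant`, so seeds are grouped by anti-diagonal
   (tolerance `band`, default 600 bp) and split where consecutive seeds
   are more than `max_seed_gap` (2 kb) apart.
3. **Extension.** Chains extend outward base-by-base (plus end pairs with
   minus start) exactly, then in blocks tolerating mismatches, and the
   final arm pair is verified by global alignment (edlib); hits below
   90% identity or 1 kb are dropped.
4. **Assembly.** Hits are accepted greedily — longest first, ties broken
   by identity then separation — rejecting any hit that re-uses claimed
   sequence. Accepted hits nested inside one another share a center and
   merge into one multi-shell palindrome; the innermost gap is the
   spacer (reported unidentified when the inner arms abut). Secondary
   hits whose free side is a sub-arm-length partial copy outside every
   palindrome become pre-arms.
5. **Arm divergence profiles** count alignment differences in 100-bp
   windows of the arm–arm global alignment; per-window differences sum
   exactly to the alignment's total difference count.

## Gene-conversion signatures

Collapsed mapping of all arms of two sister species onto one arm copy
yields sites with per-species ref/alt depths. Sites pass a quality ≥ 20
and depth ≤ 300 filter (idempotent). With `m` of the 4 collapsed copies
carrying the alternate allele, the expected allele fraction is `m/4`, so
fractions within ±0.15 of {0.25, 0.5, 0.75} are PSV-like and fractions
within 0.15 of 0 or 1 are near-fixed. Classes: fixed interspecific
difference (both species near-fixed, opposite), shared variant (PSV in
both), species-private PSV, other. Converted-region detection scans
100-bp density tracks for runs with PSV count ≤ 0 (configurable),
requires a total fixed-difference floor over the run and, optionally, a
mean relative depth inside [3N, 5N], where relative depth is
`depth / genome_mean × 2` (collapsed four-arm coverage ≈ 4N).

## Z–W homology and dS

Protein search: Smith–Waterman (BLOSUM62, gap open −11 / extend −1) over
pairs prefiltered by shared amino-acid 4-mers; E-value proxy from fixed
Karlin–Altschul parameters (λ = 0.267, K = 0.041). Mutual best hits
require reciprocal best status plus > 90% identity over ≥ 70% of the
query in both directions. Tandem arrays: single-linkage clustering of
intra-genome hits with E ≤ 1e-10 whose starts lie within 500 kb on one
chromosome. W genes are assigned one category by fixed priority:
ZW_homolog > tandem_duplicate > transposed_from_autosome > ancestral
(significant outgroup hit on the homologous chromosome) > non_mutual >
no_hit.

dS/dN uses protein-guided codon alignment and the Nei–Gojobori (1986)
estimator: per-position synonymous-site fractions with mutations to stop
codons excluded from the normalization; differences averaged with equal
weight over all orderings of the changed positions, discarding orderings
that pass through a stop codon unless all do; Jukes–Cantor correction
`d = −3/4 ln(1 − 4/3 p)` with saturation flagged at p ≥ 3/4. Strata:
dS values ordered along the Z coordinate are segmented by penalized
least-squares mean-shift (dynamic program; default penalty
`2·var·log n` per extra segment); the segment count is the number of
inferred strata.

## LTR insertion dating

Candidate elements are direct-repeat pairs found by exact 24-mer seeds
on a shared diagonal, clustered, extended, and verified by global
alignment (≥ 85% identity, repeat length 0.1–5 kb, separation 1–20 kb).
Element boundaries are pinned by the longest exact 5–20 bp target-site
duplication within ±8 bp of the repeat ends. Overlapping candidates
resolve to the higher identity × length score.

Divergence between the two repeats is computed after complete deletion
of gapped alignment columns. With transition proportion P and
transversion proportion Q:

* K2P: `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`
* gamma-K2P (shape a): `d = (a/2)[(1−2P−Q)^(−1/a) − 1] + (a/4)[(1−2Q)^(−1/a) − 1]`

Insertion age is `T = d / (2μ)` with μ = 2.5e-9 substitutions/site/year
(d = 0.043 → 8.6 My). Uncertainty comes from a multinomial bootstrap of
alignment-column categories (match / transition / transversion).
Elements whose internal region carries both gag- and pol-related domains
are autonomous.

## Synthetic data

The simulator builds `W = PAR1 + SDR + PAR2` with the Z sharing the PARs
byte-identically and the SDR backbone diverged by a configurable
Z–W distance. Into the W SDR it plants hemizygous insertions, a
two-palindrome block (pre-arm, arm1–spacer–arm2, and a nested
four-shell palindrome), and LTR elements with exact TSDs. Arms descend
from one template through per-palindrome consensus sequences, so
within-palindrome divergence (default 0.002) is much smaller than
cross-palindrome divergence (default 0.01) — the pattern maintained by
ongoing arm conversion. Conversion tracts overwrite each species' arms
with that species' consensus, producing the PSV-free, fixed-difference
signature. Substitutions follow a Poisson events-per-site model (so
distance corrections apply exactly); read depths are Poisson with
per-base copy number; pooled GBS intervals and collapsed-arm pileups are
generated with the same ledger. Every planted feature is recorded, which
is what the recovery tests and the acceptance script score against.
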