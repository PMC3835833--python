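# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Count model and the two-library test

The design is a pooled two-library comparison: RNA from several
biological repeats is mixed into one library per condition, so there is
no replicate-level variance estimate and differential expression must
come from the counts alone. When each gene occupies a small fraction of
its library, the count x of a gene in a library of N clean reads is
Poisson. Conditional on x in library 1, the probability of y in
library 2 is

    p(y|x) = r^y (x+y)! / [x! y! (1+r)^(x+y+1)],   r = N2/N1,

equivalently a negative binomial with x+1 successes and success
probability N1/(N1+N2). The two-sided p-value is the doubled smaller
tail, p = min(1, 2·min(P(Y≤y|x), P(Y≥y|x))); a one-sided option is
exposed (`alternative="less"/"greater"`).

Numerics: the pmf is evaluated in log space with `gammaln`; tails are
summed over k = 0..K where K extends 12 standard deviations past both
the conditional mode r(x+1) and y, leaving < 1e-16 of unaccounted mass.
Doubling the smaller tail can exceed 1 in exact arithmetic (the two
tails share the point mass at y), so values within 1e-12 of 1 are
snapped to exactly 1.

A caveat discovered while property-testing: the conditional
construction is **not exactly exchangeable** — swapping (x, N1) with
(y, N2) changes the tail index sets, and at very small counts the two
p-values can differ by up to a factor 1 + max(N1/N2, N2/N1) (e.g. at
x=0, y=1 with equal depths: 1.0 vs 0.5). The discrepancy is irrelevant
at the counts where DE decisions happen; the test suite asserts the
factor bound rather than exact symmetry.

## RPKM and the ratio floor

RPKM = 1e9·C/(N·L). N is the number of clean reads in the library
(pre-mapping), not the sum of retained counts — removing contaminant
(bacterial) genes from the table therefore does not change N. The log2
infected/control ratio clamps both RPKMs at a 0.001 floor so that
undetected genes give large finite ratios; the floor never enters the
count test, which sees raw counts. A gene is a DEG when BH-FDR ≤ 0.001
and |log2 ratio| ≥ 1, both inclusive. (The looser FDR ≤ 0.01 screen
sometimes quoted for this design is available by configuration; 0.001
is the operative default.)

BH FDR is the standard step-up: on sorted p-values, q(i) =
min_{j≥i} p(j)·m/j, capped at 1, order restored. Implemented directly
(it is four lines of numpy) and cross-checked against
statsmodels in the tests.

## Read filtering and mapping

Filters, in order, with removal attributed to the first matching rule:
adaptor present as an exact substring (read-level removal, no
trimming — the convention when adapter-carrying inserts are discarded
wholesale); N fraction strictly greater than 10%; fraction of bases at
Phred ≤ 5 strictly greater than 50%. "Strictly greater" means a read
sitting exactly on a boundary is kept.

The mapper is a deliberate brute-force stand-in for a real short-read
aligner: every clean read is scanned against every offset of every
gene, forward and reverse-complement, accepting Hamming distance ≤ 2
(the conventional mismatch budget; configurable, and "fewer than 2"
readings can use `max_mismatches=1`). Reads hitting exactly one gene
are unique, increment that gene's count and mark covered bases at the
best-scoring offset; multi-gene hits are tallied separately and do not
contribute to counts or coverage. Coverage ratio = covered bases /
gene length. N in a read never matches a reference base. No indexing,
no gaps, no quality trimming, no SAM output — at toy scale (hundreds
of reads, tens of genes) exhaustive search is exact and fast enough.

## Enrichment

Per term: p = P(X ≥ m), X ~ Hypergeometric(N, M, n), where the
universe N is the set of genes carrying at least one annotation **of
that term type** — GO and pathway analyses run as separate families,
each Bonferroni-corrected by its own number of tested terms, enriched
at corrected p ≤ 0.05. The upper tail is computed by
`scipy.stats.hypergeom.sf` (log-space binomials internally); the tests
check it against exhaustive enumeration and an urn simulation.
Sorting ties break on term_id for reproducibility. No GO-DAG
propagation and no q-value variants are attempted.

## 2-DE spot calls

Abundance is vol.% per replicate gel (3 by default, matching a
three-repeat design). A spot is a DEP when the infected/control ratio
of replicate means is ≥ 2 (or ≤ 1/2) and a Welch t-test across
replicates gives p ≤ 0.05. The test runs on log volumes when all
replicates are positive — making every call invariant to rescaling a
gel — and falls back to raw volumes when zeros mix with signal. Spots
with all-zero volumes in exactly one condition are presence/absence
calls (infected_only / control_only) with infinite fold and no test,
mirroring "x/0" table entries. Means (not medians) define the fold;
the choice is configurable in spirit but means are the default and
only implementation.

## Integration

DEP→DEG matching goes through an explicit accession→gene table; no
sequence-similarity resolution is attempted. A DEP is concordant when
its direction (presence-in-infected ⇒ up, presence-in-control ⇒ down)
agrees with at least one matched DEG. qRT-PCR folds use 2^−ΔΔCT with a
single reference-gene column — designs that name two internal
standards must pick one; the caller decides which CT column to supply.
Folds in [0.67, 1.5] (configurable) count as "no change"; a gene's
trend_match is the shared direction when both platforms agree and
"discordant" otherwise (including qPCR-flat vs RNA-seq-called genes).

## Synthetic generator

What it emulates, per seed (numpy `default_rng`, one independent
stream per stage so stage outputs do not depend on call order):

- **Expression truth**: lognormal (σ = 1) true RPKM, normalised so
  Σ RPKM·L = 1e9, i.e. expected library totals equal the configured
  sizes (10⁶ reads per library by default, 2,000 genes of 300–3,000 bp).
- **DE planting**: 10% of genes DE by default, fold drawn from
  {10, 0.1} applied in the infected library only. One GO term and one
  pathway term are "planted" enriched: 80% of their 25 members are
  forced DE before the rest of the DE set is drawn uniformly.
- **Counts**: Poisson around RPKM·FC·N·L/1e9 — exactly the model the
  test assumes; a gamma-Poisson (negative binomial) switch
  (`overdispersion`) exists for sensitivity work but is off by
  default, because the emulated design states the Poisson model.
- **Reads** (optional, toy scale, default 2,000 × 49 bp — the read
  length implied by dividing the design's printed base total by its
  read total): uniform gene/position sampling, substitution errors,
  and disjoint planted fractions of adaptor-carrying (a fixed 13-mer;
  real adapter sequences vary and none is canonical here), high-N
  (20% N) and low-quality (60% of bases at Phred 2) reads, each
  designed to trip exactly one filter.
- **Spots/qPCR**: replicate vol.% lognormal around condition means
  (CV 10%), planted up/down spots at fold 4, presence/absence spots,
  and CT values built to invert 2^−ΔΔCT exactly (reference CT 20,
  target CT 25 in control).

What it does **not** emulate: positional coverage bias, GC/length
effects, biological replicate variance (the design pools replicates
before sequencing — hence one library per condition and no
replicate-aware count model), multi-mapping homology structure beyond
random sequence collisions, gel-to-gel registration error, or qPCR
efficiency ≠ 2. Passing tests therefore demonstrate correctness of the
statistics under their own assumptions, not robustness to real-data
violations of those assumptions (overdispersion in particular: under
real biological replication the pure-Poisson test is anticonservative).

## Problem sizes

Unit tests run at 60–500 genes and hundreds of reads. The calibration
and power checks use the default study conditions — 2,000 genes, 10⁶
reads per library, 20 seeds for both the global-null and the
10%-DE-at-tenfold runs — sizes at which the whole suite completes in
about a minute on one CPU while leaving the binomial tolerances tight.

## Known limitations

- The brute-force mapper is O(reads × genome); it exists for exactness
  at toy scale, not throughput.
- P-values printed by historical pooled-design studies are not
  recoverable gene-for-gene without their exact mapped totals N1, N2
  per gene universe; the package validates its statistics against
  exact oracles and ground-truth recovery instead.
- Bonferroni is the only multiple-testing correction offered for
  enrichment (no permutation q-values).
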