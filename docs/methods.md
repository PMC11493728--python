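# Methods

## Selection model

The generator treats a CSR round as deterministic exponential amplification
followed by sampling: a variant with per-cycle amplification efficiency
w ≥ 0 grows by (1 + w) per cycle, so after `cycles` rounds (default 20,
the usual CSR thermocycling depth) its expected post-selection frequency is

    post_m ∝ pre_m · (1 + w_m)^cycles

normalized over the library, and observed counts are a multinomial draw of
`post_depth` reads from those frequencies. Compartment occupancy, template
exhaustion and recovery-PCR chemistry are deliberately not modeled: the
exponential model is the simplest one that produces the log-linear
enrichment the downstream score assumes, and the analysis only ever sees
its sampled counts. The closed-form enrichment
E_true = ln(post_m / pre_m) is recorded per variant for parameter-recovery
tests.

## Reference study conditions

`default_scenario` fixes the conditions every end-to-end test runs under:
a 2-point saturation library (positions 403/404, NNK at the DNA level,
genotypes tracked at the protein level; 20² = 400 variants, stops
excluded), uniform pre-selection pool, 10 designated winners with w
linearly spaced 0.12–0.30, 20 cycles, 10⁵ reads per round. With those
fitnesses the winners jointly take ≈ 63 % of the post-selection pool
(individual post frequencies ≈ 1–19 %), leaving the 390 background
variants at ~10⁻³ post frequency. The spread of w values gives the
estimated-vs-true enrichment correlation genuine within-winner signal, and
the realistic background residual is what makes the coverage analysis
informative: at starved post-selection coverage a background variant drawn
twice by the with-replacement subsampler can spuriously test as enriched,
which is exactly the false-positive mode unbalanced grids are known for. A
single shared winner strength near saturation (e.g. w = 1, which leaves
the background at 10⁻⁷ post frequency) would make winners trivially
detectable at any coverage and false positives structurally impossible.

The synthetic 664-bp amplicon is a frozen pseudo-random backbone with
KOD-style residues pinned at protein positions 403–409 (L, D, F, R, –, L,
Y; frame offset 2, first codon = position 343), so genotype labels carry
the familiar L403/D404 coordinates.

## Read emission and error model

Each read is its variant's full-length amplicon (WT with the targeted
codons replaced by the scheme's lowest-sorting codon for the variant amino
acid) passed through per-base error processes:

* pre-selection reads carry baseline sequencing/PCR noise only —
  substitutions 5.60×10⁻⁴/bp, deletions 2.20×10⁻⁴/bp, insertions
  9.7×10⁻⁶/bp (≈ 7.9×10⁻⁴ errors/bp total), the published pre-selection
  amplicon spectrum for this assay class;
* post-selection reads additionally carry a per-variant polymerase
  spectrum, default substitutions 7.15×10⁻³/bp with small indel terms, so
  raw post totals land near 8×10⁻³ errors/bp (~10× baseline), matching
  the magnitude such selections report.

Substitutions are transitions with probability b/(1+b) where b is the
transition:transversion count ratio (default 2:1); transversions split
equally. Indel rates are in bases/bp; a fraction `frameshift_frac` of
events (default 0.04 in the study conditions) has the configured
`indel_length` (1 bp ⇒ frameshifting) and the remainder is emitted as
3-bp frame-preserving events. This split exists because the published
per-base indel rates and the published frameshift-read frequencies are
irreconcilable if every indel event were 1 bp: 2.2×10⁻⁴ deletion bases/bp
as 1-bp events would frameshift ~13 % of 664-bp reads, while ~0.5 % is
observed. Quality strings are constant ('I'); the analysis never reads
them. Emission order is variants sorted by label, so a fixed seed gives
byte-identical FASTQ.

What the generator does **not** emulate: paired-end structure and merging,
quality-dependent errors, homopolymer-specific indels, PCR jackpotting /
chimeras, emulsion occupancy statistics, and strand asymmetries. Passing
tests therefore demonstrate the statistical machinery on an idealized
error process of the right magnitudes, not robustness to every artifact of
real libraries.

## Genotype calling

Reads are globally aligned (edit distance, edlib) to the reference with
the targeted codon windows wildcard-masked to N. Masking is load-bearing:
under unit costs a 2–3-substitution codon change ties with an
insertion+deletion pair, and an aligner is free to return the indel form,
which would disrupt the window it sits in; with the window wildcarded the
variant codon aligns at zero cost and indels inside windows are real.
Windows are then extracted *through* the alignment (upstream indels cannot
shift them) and translated. A read is rejected — rejections are data — for
an indel inside or within 3 bp of a window (optimal gap placement is
ambiguous up to that guard), an ambiguity code in a window, a stop codon
at a targeted position, or edit distance above 30 % of the reference
length after a reverse-complement retry. Frequencies use callable reads
only, which keeps them summing to 1.

## Enrichment and the E-test

Scores use a 0.5 pseudocount on both counts when either is zero (score
only; the test always uses raw counts); both-zero variants are dropped.
The E-test p-value is the exact double sum over outcome pairs under the
pooled rate, each marginal truncated at mean ± max(10√mean, 50) (omitted
tail mass < 10⁻⁸), vectorized over the outcome grid; the observed pair's
own probability is a lower bound so p ∈ (0, 1] always. At small pooled
means (λt ≈ 10) the test is conservative — empirical size ≈ 0.035 at
α = 0.05 — as exact-style unconditional tests are. α defaults to 0.05,
two-sided, no multiple-testing correction (a Benjamini–Hochberg flag
exists); a minimum post-selection count is available as a reporting
filter, never as part of classification. Records sort by E descending,
ties by post count then label.

When published tables print counts and scores but not totals, the
total-ratio offset ln(N0/N1) is recovered from any one trusted row as
E_ref − ln(c1/c0) and applied to the rest; this is insensitive to whether
the original totals included rejected reads.

## Fidelity profiling

Fixed affine scoring: match +1, mismatch −1, gap open −2, gap extend −1
(a k-length gap scores −(2 + (k−1))); the first optimal alignment of
Biopython's `PairwiseAligner` is taken, which is deterministic, and a
mismatch always beats a gap pair under these costs. Excluded windows
(targeted codons for per-mutant profiles) are wildcard-masked in the
alignment target for the same reason as in calling. A read is frameshifted
iff its net coding-region indel length is not a multiple of 3; such reads
enter the frameshift frequency but not rate aggregation, since their
alignments smear errors. Corrected total = total − baseline total; fold =
round(total / baseline total) to the nearest integer, the convention that
reproduces published fold columns (corrected/baseline does not). The 4×4
spectrum is normalized per reference-base opportunity; transitions are
A↔G and C↔T.

## Coverage subsampling

Coverage is interpreted at the read level (the subsampling unit);
`reads_for_coverage` is ceil(C × library size). Reads are drawn with
replacement (a without-replacement flag exists for sensitivity checks);
because calling is deterministic per read, subsampling operates on
pre-called labels, which is equivalent to re-calling sampled reads and
removes the dominant cost from the trial loop. Trial seeds are spawned
from the master seed via `numpy` SeedSequence with a counter, so every
(pair, trial) stream is independent and reproducible. The truth set is
the enriched set of the full, unsubsampled analysis. TP (FP) is the mean
detection probability over truth (ever-detected non-truth) mutants;
precision = TP/(TP+FP), NaN-flagged when both are zero. Statistical
comparisons (e.g. balanced vs unbalanced grids) average precision over 10
subsampling master seeds, since a single 10-trial grid leaves the
comparison within its own sampling noise.

## DoE factor importance

Responses are background-corrected (divide for densitometry, subtract with
clamping at zero for spectrophotometric readouts) against the
negative-control mean, then min–max scaled to 0–100 %. Continuous factors
are standardized before expansion; categoricals are one-hot coded against
the first declared level; interactions are all pairwise products and
quadratics add squares of continuous factors; constant columns are dropped
with a warning. Each of the (default 100) repeats reshuffles a 5-fold CV
split, picks λ minimizing CV error over a log-spaced 100-value grid
(scikit-learn `LassoCV`), refits on all runs, and records coefficients,
λ, and in-sample R², MSE, MAE plus AIC/BIC with the number of nonzero
coefficients as effective degrees of freedom (the standard Lasso df
estimate) — in-sample because the screens this serves have two dozen runs.
Rows are canonicalized (lexicographic sort) before fold assignment, so the
output is invariant to design-row order and bit-reproducible under a fixed
seed. A degenerate (zero-variance) response returns all-zero coefficients.
Boruta is not reimplemented; the Lasso path never depends on it.

## Problem sizes

The test suite runs the full pipeline at 10⁵ reads/round (one shared
simulation fixture; genotype calling is performed once and reused),
subsampling grids at N = 10 trials per coverage pair, 10,000 null
simulations for E-test size, and 50 random instances against the
brute-force E-test oracle; the analysis drivers default to 2×10⁴
reads/round and a 4,000-read fidelity cap, which reproduce the same
qualitative results in seconds to a couple of minutes per script.

## Known limitations

* The exponential selection model has no compartment-level saturation, so
  very strong winners can dominate more than real emulsions allow.
* Per-mutant fidelity attributes all read errors to the called variant;
  reads miscalled because an error hit a targeted codon carry their errors
  to the wrong profile (a ~1 % effect at the default rates).
* The E-test p-values are unadjusted across the 400-variant family by
  default, mirroring common practice for these screens; enable the BH flag
  when the enriched list feeds expensive downstream validation.
* Published-table reconstructions inherit the tables' own 2-decimal
  rounding; one unit in the last digit is the attainable agreement for
  rows whose WT calibration compounds two rounded values.
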