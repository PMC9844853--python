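# Methods

`cistromics` implements the statistical chain used to connect a pair of
transcription-factor (TF) cistromes to their downstream transcriptome and
to disease-associated regulatory variation: co-occupancy testing against a
covariate-matched permutation null, integration with knockdown
differential expression, LD-based candidate-variant scanning with
allele-aware motif scoring, and allelic-imbalance (AI) testing at
heterozygous regulatory SNPs.

## Coordinates and data model

All in-memory coordinates are 0-based half-open (BED convention).  BED
input is consumed as-is; header-declared TSV interval tables are treated
as 1-based inclusive and converted on read (and back on write), so both
formats round-trip exactly.  Strand is carried on intervals but ignored by
overlap and distance computations, which are strand-agnostic.

The differential-expression table carries both `log2_fc` and a signed
linear `fold_change` (`FC = 2**l2fc` for up, `-2**(-l2fc)` for down;
negative = down in the knockdown).  Filtering operates on the linear
scale (`|FC| >= threshold`, inclusive at the boundary) with a BH-adjusted
p cutoff; the defaults are |FC| 1.5 and FDR 5%.  Genes with missing fold
change or adjusted p (e.g. independent-filtering artifacts) are excluded
from threshold filtering but retained in rank-based shift tests, which do
not threshold on significance.

## Peak-to-gene assignment

Peaks are assigned to the gene with the nearest transcription start site.
The distance anchor is the peak summit when the peak caller provides one,
else the midpoint.  Distances are unsigned; equidistant ties resolve to
the lexicographically smallest gene id, which makes the assignment
deterministic and invariant to annotation ordering.  Peaks on contigs with
no annotated TSS are flagged, never silently dropped.  An optional
`resize_to_summit` transform standardizes peaks to a fixed half-width
around the anchor for analyses that prefer a uniform (~200 bp fragment)
resolution; overlap analyses default to raw peak widths.

Overlap between two peak sets is counted from the query side: a query peak
counts once if it shares at least `min_bp` bases (default 1) with any
subject peak.  This asymmetric convention is what makes "fraction of A
peaks also bound by B" well defined.

## The matched permutation null for co-occupancy

Peaks concentrate in accessible, GC-rich, promoter-proximal DNA, so a
naive uniform-shuffle null wildly overstates co-occupancy significance.
The null here draws random region sets that

1. lie entirely within open chromatin (e.g. ATAC-seq intervals),
2. reproduce the query set's GC-content profile, and
3. reproduce its distance-to-nearest-TSS profile,

with matching *joint* over (GC bin, distance bin) — the conservative
reading when both constraints apply to the same random sets.  Each null
draw reproduces the query set's cardinality and joint bin counts exactly;
lengths are resampled with replacement from the query length distribution.
Defaults: GC bins of width 0.05, distance bins log10-spaced from 1 bp to
10 Mbp plus an overflow bin, with the lowest bin extended down to zero so
a peak sitting exactly on a TSS does not create a 1-bp-wide cell that
rejection sampling could only fill by coincidence.  Both binnings are
configurable; fine bins demand a sampling universe large enough that every
occupied joint cell has appreciable probability mass (see "Problem sizes"
below).

Sampling is by rejection: candidate windows are drawn uniformly inside
open chromatin (interval chosen proportional to its length, start uniform,
draws that do not fit are rejected) and accepted while their joint bin has
unfilled quota.  Candidates are generated in vectorized batches and banked
per bin across permutations; because candidates are i.i.d. from a proposal
that does not depend on the quota state, banking changes nothing
statistically while removing the coupon-collector cost of refilling rare
bins for every permutation.  A draw budget (default 10,000 x set size per
permutation) turns an unfillable bin into an informative error.  Sampled
intervals may overlap one another within a draw; the generating process
for real peak sets has no such exclusion either.

The statistic is the query-side overlap with the genuine second set, and
the empirical p uses the add-one convention
`p = (#{null >= observed} + 1) / (N + 1)` (Phipson–Smyth), giving a floor
of `1/(N+1)` at N permutations: p below 1e-5 is only reachable with at
least 1e5 permutations.

Under the synthetic null the observed set is itself a draw from the
proposal, so conditional on its bin profile the observed and null counts
are exchangeable and the empirical p is uniform up to the discreteness of
overlap counts — the calibration property the test suite checks.

## Target-set shift testing

Whether a candidate target-gene set is down-shifted is tested with a
Wilcoxon test on log2 fold changes: two-sample rank-sum of targets versus
all other genes (default) or one-sample signed-rank against zero.  Exact
null enumeration is used for small samples (n <= 25, no ties), otherwise
the normal approximation with continuity correction.  The two-sample
default is used because the alternative background (all non-target genes
in the same table) is explicit and the test is invariant to monotone
transforms of the fold-change scale.

## Variant scanning

LD between variants is the squared Pearson correlation of dosage vectors
over samples non-missing at both SNPs (genotypic, unphased r²; phased
haplotype estimators such as PLINK's composite/EM variant will differ
slightly).  Monomorphic columns raise a distinct error from
insufficient-data cases.  Tag-SNP expansion takes, per tag, all SNPs
within a 1 Mbp window (a common LD-scan convention) with r² strictly
greater than the threshold (default 0.7), unioned and deduplicated across
tags.

A SNP is inside a peak when `start <= pos < end` (half-open).  A candidate
"hit" must fall inside every supplied cistrome.

Allele effects on a position weight matrix (PWM) are log-odds scores in
bits, `sum log2(P_pwm(base)/P_bg(base))`, maximized over all windows of
PWM width covering the SNP on both strands.  The default `delta` is
evaluated on the window/strand pair that maximizes the *reference*-allele
score — it measures disruption of the existing best site.  A `max` mode
compares the two per-allele maxima instead; only that mode is exactly
antisymmetric under allele exchange, which is the property the tests
assert.  PWM counts are normalized with a pseudocount distributed in
proportion to the background and totalling `4 * pseudocount` per column
(per-cell `pseudocount` under the default uniform background, i.e.
`(c + pc)/(sum + 4 pc)`); the default pseudocount is 0.8.  Scores are
reported raw, without a p-value calibration, and no motif-call threshold
is imposed.

## Allelic imbalance

Reads at a heterozygous SNP are filtered (non-duplicate, properly paired,
MAPQ >= 10 — a read at exactly MAPQ 10 is retained), counted per allele
(bases matching neither allele, including N, are tallied separately and
excluded), and tested per donor with an exact binomial test against a 1:1
null.  The two-sided p uses the minimal-likelihood convention (sum of
outcome probabilities no larger than the observed one); at p0 = 0.5 it is
symmetric under allele exchange, so ref-vs-alt orientation is immaterial.
Donors are combined by Fisher's method, `-2 sum ln p ~ chi-square(2k)`.
The two-sided choice is pinned down by the published worked case: counts
of 15:5 and 12:4 give per-donor p of 0.0414 and 0.0768 and a combined p of
0.021, whereas a one-sided reading gives ~0.006.  Reference-bias avoidance
(N-masking the SNP base before alignment) is supported through
`mask_base`; alignment itself is out of scope — the module consumes
aligned records or bare counts.

A consistent direction across k independent replicates is scored with a
one-sided sign test, `P(X >= k_consistent)`, `X ~ Binomial(k, 1/2)` —
`0.5**k` when all replicates agree.

Fisher's method is only monotone in the number of combined replicates for
informative p-values (p below ~0.28); replicating a p near 1 *weakens* the
combination.  The property tests state monotonicity for p <= 0.25 and
assert the dilution behaviour above the crossover.

## Synthetic data and what it does (not) emulate

All generators are pure functions of a `SimulationConfig` whose mandatory
seed feeds per-stage named random streams (so adding a stage never
perturbs earlier ones); outputs are byte-identical per seed, and each
generator returns its planted truth.

* **Genome**: contigs built from equal-length GC strata (default 0.35 /
  0.50 / 0.65 at 2 x 1 Mbp) — enough compositional heterogeneity to make
  GC matching non-trivial.  Open chromatin covers ~8% of the genome as
  exponential-length intervals (~1 kb mean), an ATAC-like fraction; TSSs
  are uniform (300 genes).
* **Peak sets**: lengths ~ Normal(200, 40) clipped at 50 bp, placed inside
  open chromatin; a configured fraction of set A is planted to overlap a
  set-B peak by at least 1 bp.  Defaults (500 / 1,500 peaks, 65% planted
  A-side overlap) mirror the relative scale of a small and a large
  cistrome with strong co-occupancy.  Note that chance co-occupancy is
  governed by B's footprint within open chromatin: when B saturates the
  accessible universe, chance overlap is high regardless of planting, so
  power/calibration analyses use sparser configurations.
* **DE table**: null genes have log2FC ~ Normal(0, 0.3) and adjusted p
  uniform on (0.1, 1); planted genes get a ±3 log2 shift and adjusted p of
  1e-10..1e-6.  This emulates the *structure* of a DESeq2 output, not its
  count-level noise or p-value dependence on expression strength.
* **Genotypes**: within an LD block each SNP copies a latent diploid
  haplotype pair with per-chromosome probability q (else an independent
  allele), giving allele correlation q² and dosage r² ~ q⁴; the default
  q = 0.975 targets within-block r² ~ 0.9.  This is a caricature of LD
  (no recombination gradient or allele-frequency spectrum).
* **Allelic reads**: per donor, `depth` reads carry the reference allele
  with probability r/(1+r); a configured fraction receives a disqualifying
  flag (low MAPQ, duplicate, or unpaired) to exercise the filters.  Truth
  records post-filter counts.  Defaults (depth 20, ratio 3, two donors)
  match the worked study case; no sequencing-error model is included.
* **Full study** (`gen_study`): ties the pieces together — down-regulated
  targets planted among genes nearest to co-bound peaks, one risk SNP
  embedded in a consensus motif match inside an A∩B overlap region (C
  fits the consensus, T breaks it), het-donor pileups at that SNP.  The
  motif is a synthetic homeodomain-flavoured consensus (TAATCA core), a
  labelled stand-in rather than a database matrix.

Passing tests on these generators demonstrate the statistical behaviour
of the methods under known truth; they do not validate peak calling,
alignment, or DE model fitting, all of which are consumed, not performed.

## Problem sizes and numerical choices

The permutation-test property checks run at a reduced scale chosen so the
statistics, not the constants, are what is exercised: calibration uses 200
replicate tests of 80 query vs 200 subject peaks on a 2 x 200 kb genome at
199 permutations with GC bins of width 0.1 (at ~80 peaks per template, a
0.05-wide joint cell can hold a single peak whose cell has vanishing
proposal mass — matching that finely requires a larger genome); power uses
100 runs of 60 vs 120 peaks with 60% planted overlap, which reaches the
floor p in every run.  Conservation of the joint bin profile is asserted
draw by draw at the default 0.05 bins.

Empirical p-values from discrete statistics are conservative wherever null
ties with the observed value occur; the add-one convention never reports
zero.  Exact binomial and rank tests switch to normal approximations above
n = 25 or in the presence of ties.  All-N sequence yields an undefined
(NaN) GC that is binned separately.  Degenerate inputs (empty DE table,
zero informative reads, monomorphic genotype columns, all-tied fold
changes) raise typed, descriptive errors rather than returning sentinel
values.

## Known limitations

* The matched sampler requires every occupied joint (GC, distance) cell to
  be reachable inside open chromatin; very fine bins on small universes
  fail fast with a diagnostic rather than silently relaxing the match.
* LD r² is genotypic; no EM phasing is attempted.
* Motif scores are raw log-odds without significance calibration.
* The AI model is a plain binomial — no beta-binomial overdispersion — and
  the pipeline tests one SNP at a time rather than scanning genome-wide.
* At depth 20 per donor with two donors, the exactly enumerated power of
  the combined AI test against a true 3:1 imbalance is 0.75 at alpha 0.05;
  detecting subtler imbalance reliably needs deeper coverage or more
  donors.
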