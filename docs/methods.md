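# Methods

This note documents the statistical models, defaults and numerical
choices behind `homeobias`, and what the synthetic-data validation does
and does not demonstrate.

## Homeolog pairing

Pairs are built by strict reciprocal best hit (RBH) between the two
parental transcript sets, from precomputed tabular alignment files
(12-column outfmt-6 dialect).  Hits are pre-filtered at ≥ 90% identity
and E ≤ 1e-50 — stringent thresholds intended to suppress out-paralog
hits between species — and "best" is defined by a total order: highest
bitscore, then lowest E-value, then lexicographically smallest subject
id.  The total order makes the pairing a pure function of the hit *set*:
input row order cannot change the result.  RBH yields a strict 1:1
mapping by construction; where one parent is polyploid and carries
duplicated copies, only the best-aligning copy enters a pair — the
package makes no attempt to recover 1:n ortholog groups, which would
require a different (e.g. score-ratio or synteny-based) criterion.
A transcript hitting itself is treated as an error (overlapping
identifier namespaces would make pairing ambiguous), not silently
dropped.

## Normalization and filtering

Counts are normalized two ways, each used where it is meaningful:

* **TPM** (length-normalized rate rescaled to 1e6 per sample) drives the
  detection filter: a transcript is "expressed" with TPM ≥ 1 in at least
  one sample (both thresholds configurable).  Because each taxon is
  quantified against its own reference, the filter is applied per count
  matrix, i.e. per taxon.  A homeolog pair enters the analysis when both
  homeologs pass the filter in the *hybrid* libraries.
* **RPKM** (`count · 1e9 / (length · mapped_reads)`) is the expression
  scale for the t-tests and the bias statistic.  Mapped-read totals per
  library are taken from an explicit table when provided; otherwise the
  column sums of the count matrix stand in, which is exact up to the
  (unknowable, shared) fraction of reads mapping outside the analysed
  transcript set.  Effective length is the full transcript length; no
  fragment-length correction is applied.  Hybrid pair totals and
  parental transcripts are compared on RPKM as-is, with no cross-taxon
  renormalization — a compositional assumption the user should be aware
  of when libraries differ grossly in makeup.

Sample QC is a pairwise Spearman matrix (average ranks for ties).  A
constant sample has no defined rank correlation; it is reported as
missing with a warning rather than an arbitrary value.

## Expression-level dominance classification

Per pair and condition, three two-sample pooled-variance Student
t-tests are run on per-replicate RPKM: hybrid total (sum of the two
homeologs per hybrid replicate) vs each parent, and parent vs parent.
"Different" means p < α (default 0.05) per test, with no
multiple-testing correction inside the classifier; "equivalent" is
fail-to-reject.  The three verdicts and the orientation of the group
means pick one of 13 patterns; the 6 operational bins (no change,
additivity, dominance toward each parent, transgressive up/down) are
the semantically robust level — the numeral orientation within a bin
follows the conventional layout (e.g. IV vs IX distinguish which parent
is higher while the hybrid tracks P1).  Two geometrically inconsistent
outcomes fold into `no_change` with a `conflict_flag`: the intransitive
triple (hybrid ≈ both parents while the parents differ) and residual
shapes such as a hybrid significantly different from two parents it
lies strictly between while the parents themselves do not differ.
Tests run on untransformed RPKM by default; a `log2(x+1)` option
exists for heavy-tailed data.

Degenerate inputs: two identical constant vectors give p = 1; zero
pooled variance with unequal means gives p = 0 with a warning (the
limit of the t statistic as variance vanishes).

An intrinsic property worth stating explicitly: under a true null, each
hybrid-vs-parent test still rejects at rate α, so even with arbitrarily
strong planted effects elsewhere, roughly `1 − (1 − α)² ≈ 9.8%` of
genuine no-change pairs are called into effect bins.  Validation tests
bound the no-change recovery by `1 − 2α` (Bonferroni) rather than
pretending the leak away; users comparing pattern proportions across
conditions should remember the no-change category carries this constant
haircut.

## Homeolog expression bias

`B = log2(mean(RPKM_spt) / mean(RPKM_spc))` over hybrid replicates
(equal replicate numbers make this the ratio of sums).  Pairs with a
zero count sum on either side at a condition are excluded from that
condition (and from any ΔHEB involving it) rather than patched with
pseudocounts; the exclusion is logged.

**Per-condition test.**  The observed split of the pair's summed reads
is modelled as binomial.  Under H0 (equal underlying expression) the
P1-homeolog share is the length-expected proportion
`π0 = len_spt / (len_spt + len_spc)`; under H1 it is the MLE.  The
statistic `2(ℓ1 − ℓ0)` is referred to chi-square with 1 df, and BH-FDR
< 0.05 (configurable) calls significance per condition.  The statistic
is computed with `x·log(x/…)` kernels under the `0·log 0 = 0`
convention and clipped at zero, so it is exact for boundary tables.

**Between-condition test.**  ΔHEB is *defined* as `B₂ − B₁`.  Its test
is the G-test of homogeneity on the 2×2 table of summed counts
({condition 1, 2} × {P1-, P2-homeolog}); length offsets are common to
both conditions and cancel, so no length term appears.  Significance
uses raw α = 0.05 (chi-square, 1 df), consistent with testing only the
consecutive contrasts in the configured condition order (an
`all_pairs` switch exists).  Both LRTs are validated in the test suite
against independent oracles: direct `scipy.stats.binom.logpmf`
evaluation, and exhaustive margin-expectation G statistics over all
2×2 tables with row totals ≤ 30.

**Known limitation — overdispersion.**  The binomial/G likelihoods
model read sampling, not biological replicate variance.  With
negative-binomial dispersion φ > 0 the summed counts are overdispersed
relative to the model and both LRTs reject too often under the null;
calibration is nominal in the Poisson (φ = 0) limit, which is what the
calibration tests use (10,000 null pairs at mean count 200 per
replicate give a rejection rate statistically indistinguishable from
0.05 and uniform p-values).  A replicate-aware beta-binomial LRT is the
natural extension and is deliberately out of scope.

## Synthetic data

The generator emulates a two-parent/F1 design: P1 and P2 quantified
against their own transcript sets, F1 against the concatenation; by
default 3 conditions × 3 replicates per taxon, mirroring a
three-temperature chilling design.  Per pair and condition a pattern
bin is drawn (default mixture dominated by no-change, with dominance
toward P2 more common than toward P1 and rare transgressive classes);
the bin fixes parental means (4-fold separation where the pattern
requires differing parents, geometric-mean-preserving) and the hybrid
total (midpoint for additivity, a parent's level for dominance, 4× past
the parental range for transgressive).  A planted bias B (Normal(0, 2)
for a biased fraction of 30% of pairs, 0 otherwise, optionally shifting
at one condition boundary to plant ΔHEB) splits the hybrid total with
P1 share `2^B / (1 + 2^B)` in expression space.  Expected counts are
`expression · length/1000` at a nominal depth of 1e6 mapped reads —
counts respect transcript length, so the length-adjusted null of the
bias LRT is exercised non-trivially — and are drawn negative-binomial
with dispersion φ = 0.05 by default (variance `μ + φμ²`; φ = 0 gives
Poisson for analytic checks).  Baseline expression per pair is a
mean-preserving lognormal (ln-SD 1.0) around the level yielding 200
expected counts at the mean transcript length.

All randomness flows from one `numpy` generator seeded by
`SimConfig.seed`; fixtures are byte-reproducible, and the committed
20-pair test asset is regenerated bit-identically from its recorded
seed as a test.

What the simulation does *not* emulate: mapping ambiguity between
similar homeologs (read "bleed-through"), assembly artifacts and
chimeric transcripts, GC/length biases beyond the linear length model,
library-composition differences between taxa, and correlated
replicates.  Passing the recovery tests therefore demonstrates the
*statistical machinery* is correct and calibrated under its stated
model, not that real hybrid data meet that model.

## Validation problem sizes

Test and validation runs use desk-scale sizes chosen to make
Monte-Carlo error small relative to the asserted tolerances: 10,000
pairs for null calibration, 1,000 pairs per planted-bias level for
estimator recovery (±0.05), 2,000 pairs for classifier recovery
(≥ 90% bin-correct at 4-fold separation and ~10% replicate CV), and a
20-pair fixture for end-to-end structural checks.
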