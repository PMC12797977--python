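# Methods

This note documents the statistical procedure `ihtseq` implements, the
choices made where the design was genuinely open, and what the simulation
evidence does and does not establish.

## Preprocessing

**Count filter.** A gene is kept only if its count strictly exceeds a
threshold (default 10) in **every** sample. The inequality is strict: a
count of exactly 10 in a single sample removes the gene. Estimated
(fractional) counts from probabilistic quantifiers are accepted; the filter
compares on the real line. The filter is idempotent and order-preserving.

**TMM normalization.** Scale factors follow the trimmed-mean-of-M-values
recipe. The reference sample is the column whose 75th-percentile
library-size-scaled count is closest to the mean of those percentiles — the
standard convention. For each sample against the reference, genes positive
in both columns contribute M (log2 ratio of scaled proportions), A (mean
log2 proportion) and an inverse-variance weight from the binomial delta
method, (N_k − x)/(N_k x) + (N_r − x_r)/(N_r x_r). The default trims are
30% from each tail of M and 5% from each tail of A (rank-based, average
ranks for ties); if fewer than 10 genes survive trimming the untrimmed
weighted mean is used with a warning. Factors are rescaled to geometric
mean exactly 1. Note a subtlety the tests exercise: scaling one column by a
constant leaves M, A and the trimmed set exactly unchanged but perturbs the
count-magnitude-dependent weights, so single-column scale invariance is
only approximate (sub-percent at typical depths); scaling the whole matrix
is exactly invariant.

**Log expression.** log2(count / effective library size × 1e6 +
pseudocount), with effective size = library size × TMM factor and a default
pseudocount of 1.0 (configurable). Whether the original analysis
log-transformed CPM or normalized counts directly is ambiguous; CPM is the
implemented (and configurable) reading, and all downstream effect sizes are
defined on this matrix.

## The integrated test

Each treatment is compared with the control using two per-gene tests on log
expression, combined into one p-value:

* **t-test** — two-sided, two-sample, pooled variance (Student); Welch is
  available by flag. Genes with zero variance and equal means in both
  groups get t = 0, p = 1.
* **Median-difference test** — the statistic is median(treatment) −
  median(control). The reference this test descends from does not spell out
  the null construction, so it is reconstructed here as a permutation null:
  all C(n1+n2, n1) label reassignments are enumerated when that number is
  at most 10,000 (70 for 4-vs-4; a seeded random-subset mode covers larger
  designs), and the absolute median differences are **pooled across genes**
  into one empirical null. Pooling is deliberate: a per-gene 4-vs-4 null
  holds only 70 values, far too coarse for FDR work; the pooled null trades
  exact per-gene calibration for resolution (a per-gene mode is retained by
  flag). p = (1 + #{null ≥ |observed|}) / (1 + null size): the add-one
  smoothing keeps p strictly positive and ties count conservatively.
* **Stouffer combination** — each two-sided p maps to a signed z,
  z = Φ⁻¹(1 − p/2) · sign(effect) (t-sign from log2FC, median-sign from the
  median difference; zero effect maps to z = 0), so discordant directions
  cancel rather than reinforce. z_c = (z_t + z_m)/√2 with equal weights;
  p_c = 2(1 − Φ(|z_c|)), clipped into (0, 1]. BH step-up adjustment across
  genes gives q.
* **DEG gate** — q ≤ 0.05 and |log2FC| ≥ 0.58, both inclusive; direction
  from the sign of log2FC, which is the difference of group means of log
  expression (treatment − control).

**Calibration caveat.** The two component statistics are computed on the
same four-vs-four samples and are strongly positively correlated (measured
r(z_t, z_m) ≈ 0.88 on null simulations). The equal-weight Stouffer sum of
correlated z-scores has variance (1 + r) > 1, so the combined p-value is
denser near zero than uniform even under the null, and BH on it does not
control FDR at its nominal level in the strict sense: on spiked
simulations the realized false-discovery proportion among called DEGs runs
around 0.15–0.20 at nominal 0.05. The marginal component p-values are
individually well calibrated (KS distance from uniform < 0.05 at 5,000
null genes), and the combiner itself is exactly calibrated on independent
inputs — the anticonservatism is purely the correlation. The procedure is
implemented as specified because it *is* the method being reproduced; in
practice the |log2FC| ≥ 0.58 gate absorbs most of the excess, and on pure
null data the fraction of genes called DEG stays near 1% (bounded by the
5% criterion the acceptance suite checks). Users wanting strict FDR
control should treat q as a ranking score, not a guarantee.

## Enrichment

One-sided over-representation per gene set: with universe size N
(default: all genes surviving the count filter), set size K after
intersecting the set with the universe, query size n and overlap k,
p = P(Hypergeom(N, K, n) ≥ k). Sets not intersecting the universe are
skipped. q is BH across tested sets; significance is q < 0.05, strict. By
default only up-regulated DEGs form the query (down- and all-DEG queries by
flag). Enrichment is self-contained — no annotation service is consulted
and no GO-graph propagation or term pruning is attempted; results depend
entirely on the supplied GMT collection. For radar display, −log10(q) is
clipped into [cap_min, cap_max]; the cap maximum is deliberately mandatory
config (no magic default), cap_min defaults to 0, and a pathway absent from
a comparison's table contributes cap_min with a logged warning.

## Simulation model

Counts are negative binomial with the quadratic mean–variance relation
Var = μ + φμ², stated explicitly to avoid the size/rate parameterization
ambiguity; φ → 0 degenerates to Poisson. Defaults emulate the target
experiment: 8 groups × 4 replicates (32 samples), per-gene baseline means
LogNormal(meanlog 5.0, sdlog 1.3) (median ≈ 150 counts, a plausible
post-filter bulk profile), constant dispersion φ = 0.1 (typical bulk
biological replicates; per-gene arrays accepted), per-sample scale factors
LogNormal(0, 0.15) (±15% library composition/depth variation), 10% of
genes DE per treatment, and true |log2FC| = 0.58 + Exponential(0.7) with
random sign, so every spiked gene is in principle detectable by the
pipeline's own fold-change gate. DE gene sets are drawn independently per
treatment and may overlap, emulating shared response genes.

What the generator does **not** model: batch effects, outlier samples,
gene–gene correlation, length/GC biases, or mean-dependent dispersion
trends. Passing tests on this generator therefore demonstrates correctness
of the algorithms and calibration under the stated model, not robustness to
those real-data features.

**Power/recovery accounting.** Recovery metrics are computed over spiked
genes that survive the count filter and enter the tested universe: a
strongly down-regulated low-baseline gene can fall below the >10-in-all-
samples filter in the treated samples and is then untestable by
construction (~25% of spiked genes at |log2FC| = 2 under the defaults).
Within the tested universe, recall at |log2FC| = 2, φ = 0.1, n = 4 is
essentially complete, and the estimated log2FC of spiked genes is unbiased
to within 0.03 (the small shrinkage comes from the pseudocount and is
negligible at these expression levels).

## Numerical choices and degenerate inputs

* p-values are everywhere constrained to (0, 1]; clipping uses the smallest
  positive normal double.
* BH is the standard step-up (cummin of p·m/rank from the largest rank),
  returned in input order, capped at 1.
* Permutation splits are enumerated in deterministic lexicographic order;
  sampled mode draws from a seeded generator held in the comparison config,
  so identical seeds give byte-identical result tables.
* Result tables are written with shortest-round-trip float formatting and
  read back with round-trip parsing, so write/read is bit-exact.
* An all-zero sample column, an empty post-filter matrix, a group with one
  replicate, a query gene outside the enrichment universe, and a missing
  reference-gene Ct are all hard errors that name the offending entity.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
desk scale: 2,000 genes × 32 samples for the calibration and recovery
studies (20 seeds for the null false-call rate and the log2FC bias study),
200 × 6 matrices for the TMM oracle comparison, and exhaustive 70-split
enumeration for the median-test oracle. These sizes were chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo
error comfortably inside the asserted tolerances.

## qPCR helper

Fold = 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference and ΔΔCt referenced to
the *mean* ΔCt of the calibrator group (the plausible reading; a single
calibrator sample is not required). Amplification efficiency is fixed at 2
— no efficiency calibration curves. Technical replicates are averaged on
the Ct scale before ΔCt. Consequences tested: adding a constant to every Ct
leaves folds unchanged, and the calibrator group's folds have geometric
mean exactly 1.
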