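# Methods

This note records the statistical models, parameter choices and numerical
conventions behind each stage, and what the synthetic-data tests do and do
not demonstrate about real data.

## Pooled shRNA screen

Counts are depth-normalised to reads per million (RPM); fold changes are
computed on condition-mean RPM with a 0.5 RPM pseudocount, which keeps
dropout shRNAs finite without reordering ranks. Gene-level hits use the
trend rule: a gene passes when at least `min_consistent` (default 5) of its
detected shRNAs share the majority sign of log2FC. Conventions:

* a log2FC of exactly 0 counts toward neither sign;
* an exact sign tie yields no direction and no pass;
* `avg_log2fc` averages over *all* detected shRNAs of the gene, not only the
  consistent ones — the conservative reading of "average fold change";
* genes detected with fewer than the expected 8 shRNAs are still scored
  against the same absolute threshold (a 5-of-6 gene can pass) and flagged
  `underrepresented`.

Significance comes from a permutation null: random same-size shRNA sets are
drawn without replacement from the whole library and the two-sided p-value
is the add-one estimator (1 + exceedances)/(1 + B) on |mean log2FC|, with
resolution floor 1/(1 + B). Without-replacement subsets are drawn by
rejection of duplicate-index rows, which is exact. Rotation-based gene-set
tests were deliberately not reimplemented; the permutation test is this
package's documented resampling null, and BH FDR is applied across genes.
Each gene draws from a sub-stream spawned deterministically from the seed,
so enlarging a library does not perturb existing genes' p-values.

Screen-design arithmetic: `cells_to_transduce = library_size ×
representation / infection_efficiency` and `minimum_maintained_cells =
library_size × representation`, both also reported at 2 significant figures
(the precision such numbers are quoted at in practice).

## Median-effect model and combination index

Fraction affected is fa = 1 − %live(treated)/%live(vehicle), clipped to
[1e−3, 1 − 1e−3] because the linearising transform log(fa/fu) is undefined
at the boundaries; apparent stimulation clips to the lower edge with a
warning. The fit is ordinary least squares of log10(fa/fu) on log10(D);
m is the slope, Dm = 10^(−intercept/m), and r the Pearson correlation of the
linearised points. IC50 is reported as Dm from this fit (one model serves
both IC50 and CI; no four-parameter logistic is fitted). A non-positive
slope is flagged as non-monotone rather than used.

CI is evaluated independently at each observed combination point with its
own fa (non-constant-ratio design, matching a one-drug-swept,
partner-fixed experiment). Replicates: fa per replicate, CI on the
replicate-mean fa, with per-replicate CI dispersion reported alongside.
Band labels: CI ≤ 0.85 synergism, < 0.9 slight synergism, ≤ 1.1 additive,
≤ 1.2 slight antagonism, above that antagonism. Only the synergism and
additive bands are conventional anchors; the "slight" labels fill the gaps
and every edge is configurable. Edges are inclusive on the synergism side.

## SLAM-seq nascent transcription

A read is nascent at ≥ `min_conversions` (default 2) T>C conversions; with
threshold 0 the nascent matrix degenerates to the total matrix. UTR-level
counts are summed per gene before testing.

Differential testing: size factors are median-of-ratios computed on the
*total* count matrix and applied to nascent counts — labelling-efficiency
differences between samples would distort factors computed on nascent
counts alone. Effect size is log2((mean_t + 0.5)/(mean_c + 0.5)) on
normalised condition means. The p-value is a Rao score test of the
condition term in an NB2 log-link model: the null common mean is the exact
H0 MLE (Newton iteration; this zeroes the intercept score and makes the
statistic exactly invariant to swapping the condition coding), the score is
U = Σ xⱼ(Kⱼ − μⱼ)/(1 + αμⱼ), and the variance is the treatment block of the
Fisher information with the intercept profiled out. Dispersions are per-gene
moment estimates pooled within condition, shrunk toward a fitted
mean–dispersion trend a₀ + a₁/μ with 6 pseudo-degrees of freedom, and
clipped to [1e−8, 10]. The statistic is referred to a t distribution with
(n_samples − 2) degrees of freedom rather than a normal: with 3 vs 3
replicates a chi-square reference is anticonservative, and the heavier
tails bring the pooled empirical false-discovery proportion on simulated
null genes within twice the nominal level (checked over 20 seeded
simulations in the test suite). Numerical agreement with any particular
external differential-expression package is *not* claimed or tested.

Classification uses FDR ≤ 0.01 and |log2FC| ≥ 1 by default (both
inclusive); the overlap input set uses the looser FDR ≤ 0.1 — both
thresholds are plain parameters.

## Nascent proteome

The filter cascade runs in a fixed order — (1) drop any record flagged
potential-contaminant, reverse or only-identified-by-site; (2) drop records
seen in the no-AHA background channel unless mean DMSO PSM / background PSM
≥ 10 (the rescue denominator is the background-channel count; the ratio
aggregation is a package choice, as is the arithmetic-mean replicate
aggregation throughout); (3) drop records with PSM = 0 in any DMSO
replicate. The flag and DMSO-zero criteria are record-local, so stages 1 and
3 commute; the cascade is idempotent on its own output.

Affected calls: reduction = 1 − mean(treated PSM)/mean(DMSO PSM), clipped to
[0, 1]; a protein is affected at reduction ≥ 0.75 (inclusive by default,
with a strict-mode flag for the > reading) or when it disappears entirely.
Overlap statistics report |A∩B| as a percentage of each parent set; the
upper-tail hypergeometric p-value over an explicit detection universe is a
supplementary addition beyond the percentages. Protein→gene mapping comes
from an explicit two-column table; no identifier inference is attempted.

## Synthetic data

The generators emulate the *structure* of the real datasets, not their
content; all rates are simulator parameters.

* **Screen**: negative-binomial counts (Var = μ + αμ²), defaults 912 genes
  × 8 shRNAs, 3 replicates per arm, baseline mean 500 reads/shRNA,
  dispersion 0.05 (typical for replicate pooled screens), planted effect
  |log2FC| = 2 on 6 of 8 hairpins of 5% depleted + 3% enriched genes.
* **Dose–response**: exact median-effect viability plus truncated Gaussian
  noise; truncation to [0, 100] reflects the physical bounds of a viability
  assay. Combination tables invert the CI equation numerically (Brent root
  on fa; the left side is strictly decreasing so the root is unique), making
  the true CI of every emitted pair known.
* **SLAM-seq**: per UTR and sample, labelled and unlabelled read numbers are
  Poisson; conversion counts per read are Binomial(n_t_sites, p) with
  p = 0.025 for labelled reads (a typical 4sU conversion efficiency) and
  0.001 for background, 25 T positions per read (QuantSeq-length reads at
  ~25% T content), 30% labelled fraction, 500 reads/UTR, 2 UTRs/gene, 10%
  of genes repressed 4-fold in the treated condition. Repression scales the
  labelled-read rate only: on a 1-hour labelling window the pre-existing
  pool is treated as unchanged.
* **Proteome**: Poisson PSM counts around a mean of 25 per replicate; QC
  artefact and background fractions of a few percent; 68% of proteins
  affected at reduction factor 0.1; rescued background binders get a weak
  background signal (mean psm_mean/50) so their untreated/background ratio
  clears 10.

Every generator draws per-gene/per-protein sub-streams from the seed, so two
runs with the same seed are byte-identical and enlarging a simulation leaves
existing entities' data unchanged.

What passing tests show — and do not. Recovery tests demonstrate that the
analysis code implements its stated rules correctly and has the expected
power under the declared noise models. They do not demonstrate robustness to
features the generators omit: alignment and SNP-induced conversion
artefacts, UTR annotation errors, non-NB count heavy tails, batch effects,
ratio compression in PSM counts, or drugs departing from the median-effect
model.

## Problem sizes and numerical conventions

The bundled test-suite and acceptance runs use scaled simulations — 120–300
gene screens/SLAM-seq panels, 1000-protein tables, 500 dose–response
fits — chosen so each recovery estimate has comfortable Monte-Carlo margin
for its threshold; the recovery of a planted 4-fold repression is measured
at 2000 reads/UTR ("high depth") where the per-gene log2FC standard error is
well below the ±0.3 check. Root finding uses Brent's method at xtol 1e−14;
the permutation estimator's add-one convention means p-values never reach 0;
BH adjustment delegates to statsmodels; hypergeometric tails to scipy. All
tables are UTF-8 TSV with '.' decimals, and readers reject malformed or
comma-decimal numerics with a row-addressed error.

## Known limitations

* The screen trend rule and permutation test assume shRNAs are exchangeable
  across the library under the null; strong gene-family structure would
  violate this.
* The NB score test with 3 + 3 replicates is approximate; the t reference is
  a pragmatic guard, not an exact small-sample distribution.
* CI confidence intervals are not computed (only per-replicate dispersion);
  constant-ratio Fa–CI curves are out of scope.
* The proteome affected-call at the 0.75 boundary is sensitive to Poisson
  noise when mean PSM counts are low; recall guarantees hold for strong
  planted reductions (factor ≤ 0.1 at mean PSM ≥ 20), not near the decision
  boundary.
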