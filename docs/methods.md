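# Methods

## The neutral null for population polygenic scores

Population-level polygenic scores are linear in allele frequencies, so if
frequencies diverge by genetic drift alone, the vector of scores across `M`
populations is approximately multivariate normal:

    Z_m = 2 * sum_l alpha_l * p_{m,l}
    Z ~ MVN(mu 1, 2 V_A F),   mu = 2 sum_l alpha_l eps_l,
    V_A = 2 sum_l alpha_l^2 eps_l (1 - eps_l)

with `eps_l` the unweighted mean of `p_l` across populations and `F` the
co-ancestry matrix — the covariance of drift-standardized frequencies
`x_l = (p_l - eps_l) / sqrt(eps_l (1 - eps_l))`. `F` is estimated as
`X X' / (L - 1)` from the same SNPs used in the scores. That choice is
conservative: selected divergence at scored loci inflates the null
covariance too. Because each `x_l` is centered with the realized
across-population mean, the estimate has `F 1 = 0` and rank at most `M - 1`.

Two tests follow. The over-dispersion statistic

    Q_X = (Z - mu 1)' F^+ (Z - mu 1) / (2 V_A)

uses the Moore-Penrose pseudoinverse restricted to F's non-null eigenspace
(eigenvalue cutoff `max(M, L) * eps_machine * lambda_max`), equivalent to
dropping one population; its null reference is chi-square with `rank(F)`
degrees of freedom. The geographic-axis statistic for a per-population axis
`Y` (latitude, longitude) is `(Y'Z - mu Y'1)^2 / (2 V_A Y'F Y)`, chi-square
with 1 df. It is invariant to centering `Y` exactly when `F 1 = 0`, which
holds for the estimated F; with a user-supplied full-rank F the raw axis is
used as given. A decomposition of `Q_X` into squared projections on F's
eigenvectors shows whether a rejection loads one axis of structure or is
spread diffusely.

p-values are parametric (chi-square) only; the score's linearity and the
common-variant ascertainment make the MVN approximation accurate at the
drift depths considered here.

## tSDS

Raw SDS is standardized to mean 0, SD 1 within 5% minor-allele-frequency
bins (half-open bins; the top bin closes at 0.5; SNPs with MAF < 5% are
removed first, matching the filtering of published scores). Standardization
precedes polarization: the bin composition depends only on frequency, not on
the GWAS, so the order matters only for which SNPs exist at polarization
time, and standardizing first keeps the bin moments exact. tSDS is then
`+SDS` where the derived allele is the trait-increasing allele and `-SDS`
otherwise; SNPs with an exactly zero effect have no trait-increasing allele
and are excluded with a logged count.

The tSDS-versus-significance curve averages tSDS over consecutive bins of
1000 SNPs ordered by GWAS p-value (ties broken by chromosome, position); a
final partial bin is kept and flagged. Significance of the Spearman
correlation between tSDS and `-log10 p` uses a delete-one-block jackknife:
SNPs in concatenated genomic order are cut into `b = 200` contiguous blocks
(first `n mod b` blocks one SNP larger), the correlation is recomputed with
each block deleted, and

    se^2 = (b - 1) / b * sum_i (rho_(-i) - rho_bar)^2,

with a two-sided p-value from `rho_hat ~ N(0, se)` under the null. For
tie-free data the leave-block-out correlations are computed exactly in one
vectorized pass (leave-out ranks are full-sample ranks minus per-block
below-counts; the reduced rank margins are exactly `1..n'`, giving
closed-form moments); with ties the implementation falls back to per-block
recomputation. The two routes are asserted equal in the test suite.

## LD Score regression, lite

The engine fits `E[y_l] = a + b * l2_l` by weighted least squares with
weights `1 / max(l2, 1)` — the dominant heteroskedasticity term of the
standard estimator; the full iteratively-reweighted scheme is deliberately
out of scope. The univariate fit is two-step: the intercept is estimated on
SNPs with statistic below a chi-square cutoff (default 30, robust to large-
effect loci), then the slope on all SNPs with that intercept fixed.
Bivariate fits of products of normalized statistics are single-step and the
intercept is never constrained, because an LD-independent shared component —
sample overlap or shared stratification — is exactly what the intercept is
for. Standard errors for every fitted quantity come from a delete-one-block
jackknife over 200 contiguous blocks, computed from per-block sufficient
statistics (O(blocks) after one data pass).

Inputs that correlate mechanically with allele frequency (effect sizes, SDS,
frequency contrasts) are first normalized to mean 0, SD 1 within 1%
reference-MAF bins. Genetic correlation is
`rg = slope(z1 z2) / sqrt(slope(z1^2) slope(z2^2))`; all three regressions
use one matched single-step estimator on identical blocks, so the delete-one-
block rg values are internally consistent and `rg(self, self) = 1` exactly —
a two-step univariate fit with a cutoff would break that identity. Default
region masks exclude the HLA, LCT and chromosome-8-inversion loci (BED,
configurable).

The confounding demonstration is the package's point: give two statistics a
shared LD-independent structure component and the bivariate intercept rises
while the slope stays null; additionally inflate both statistics' variance
proportionally to LD Score — the signature of background selection, which
purges linked neutral variation and so accelerates drift in high-LD regions —
and a spurious positive slope emerges. The slope is therefore only evidence
of genetic covariance when drift is LD-independent.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure of the pipeline's inputs,
not their biology:

* **Co-ancestry.** `gradient`: populations on a line with
  `F_ij = depth * decay^|i-j|` (positive-definite, monotone decay, evenly
  spaced latitudes/longitudes); `tree`: a random bifurcating population tree
  with exponential branch lengths (mean `depth`), `F_ij` = shared root-path
  length; arbitrary trees can be supplied as newick. Default
  `depth = 0.005`, the scale of European F_ST.
* **Frequencies.** Ancestral frequency uniform on (0.10, 0.49), population
  frequencies `MVN(eps 1, eps (1 - eps) F)` clamped to [0, 1]; SNPs fixed in
  all populations are redrawn up to 10 times, then dropped with a log
  record. The MAF range is bounded away from 0 so the Gaussian drift
  approximation (which ignores boundaries) is accurate and clamping is rare.
* **GWAS.** Estimated effect = true effect + `b * a_l` + noise, where `a_l`
  is the standardized frequency contrast between the first and last
  population (the synthetic analogue of a north-south axis, configurable)
  and the noise variance is `1 / (2 N eps (1 - eps))` — the standard
  approximation for a marginal regression estimate; true effects are
  Gaussian with `2 L alpha^2 eps(1-eps)` summing to the target
  heritability of a unit-variance trait.
* **SDS.** On the counted-allele scale, `coupling * a_l` plus noise with
  variance equal to the per-SNP background-selection inflation (>= 1);
  re-signed to a randomly assigned derived allele and left unstandardized
  (standardization is the tSDS module's job).
* **LD Scores.** `1 + Gamma(shape 2, scale 50)`: positive, right-skewed,
  mean ~101 — the scale of genome-wide human LD Scores.
* **Background selection.** Divergence redrawn with per-SNP drift variance
  multiplied by `inflation_fn(l2) >= 1`. The linear family `1 + c * l2` is a
  deliberately simple stand-in for the qualitative mechanism (drift
  accelerates with LD Score); no claim is made about the exact functional
  link between background-selection strength and LD Score.
* **Sibling pairs.** Two subpopulations with distinct allele frequencies,
  parents binomial, children by Mendelian transmission, phenotype = genetic
  value + group offset + Gaussian noise. Within-pair regression of phenotype
  differences on allele-count differences (through the origin, t-based
  inference, SNPs without within-family variance flagged missing) is immune
  to the group offsets; pooled per-SNP OLS is the vulnerable comparator.

Not emulated: linkage disequilibrium between simulated SNPs (SNPs are drawn
independently, so "LD Score" is a label attached for regression purposes,
and block-jackknife robustness to real LD is exercised only through the
estimator's mechanics), haplotype-level singleton structure, allele-
frequency-dependent architectures, and ascertainment noise beyond winner's-
curse-free lead-SNP selection. Passing tests therefore certify the
statistical machinery and its calibration under the stated generative
models, not performance on any real cohort.

All randomness flows through numpy Generators; every operation accepts an
integer seed or a Generator, fixed seeds give bit-identical output, and
named substreams derived from one master seed let pipeline stages be rerun
independently.

## Numerical and design choices

* MAF bins are half-open `[k w, (k+1) w)` with the top bin closed at 0.5;
  z-scoring uses the sample SD (ddof 1), making re-standardization exactly
  idempotent.
* Ties in GWAS p-values are broken by (chromosome, position) so sorts and
  lead-SNP ascertainment are deterministic; lead-SNP MAF filtering is strict
  (`MAF > threshold`) in the designated reference population.
* Allele harmonization flips the sign of the second table's signed columns
  when its allele labels are swapped; strand-ambiguous SNPs are removed
  first. The default policy drops palindromic (A/T, C/G) pairs — the
  standard strand-safety rule; an alternative `paper-literal` policy drops
  A/G and C/T pairs instead, for compatibility with pipelines that filter
  transition pairs. Both are available because published filters disagree;
  neither is asserted as uniquely correct.
* Coordinates are 0-based half-open internally; BED is native, VCF positions
  convert on read. One convention end-to-end prevents off-by-one block
  assignment.
* Weighted least squares uses closed-form 2x2 normal equations so that
  leave-one-block refits come from per-block sufficient statistics; the
  full-sample fit is cross-checked against statsmodels WLS in the tests.
* Degenerate inputs fail loudly and specifically: zero-variance MAF bins
  name the bin, `V_A = 0` and rank-0 F raise degenerate-input errors, an
  axis in F's null space raises a degenerate-axis error, constant inputs to
  the Spearman jackknife raise an undefined-statistic error, and a perfectly
  monotone pair returns a flagged zero-variance result instead of dividing
  by zero.

## Problem sizes and calibration checks

The self-calibration experiments (`polyadapt.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 10 populations x 1000
SNPs x 100k GWAS samples with 2000 null replicates for QX and cline
calibration; 500 replicates for the stratified-versus-clean contrast, with
the bias strength set equal to the mean per-SNP sampling SD so bias and
noise are comparable; 20 000 independent SNPs x 200 blocks x 1000-1500
replicates for jackknife type-I error; 20 000 SNPs x 200 replicates for LD
Score slope recovery (planted slope 0.005, matching a modest polygenic
inflation at these LD Score scales); 300 replicates per arm of the
confounded-slope demonstration (shared structure variance 0.2); 25
replicates x 40 000 families for sibling robustness (group offset 4 trait
SDs); and 100 replicates for recovery of a planted genetic correlation of
0.8. These sizes give Monte-Carlo standard errors comfortably below the
acceptance margins while keeping a full run to a few minutes on one core.

## Known limitations

* No LD between simulated SNPs (see above); the neutral MVN model itself
  assumes unlinked, freely recombining loci.
* The two-step LD Score regression omits the iterative variance weights and
  attenuation-ratio refinements of the full estimator; intercepts and
  slopes are reported on the scale of the supplied statistics, with any
  normalization applied stated by the caller.
* Sibling simulation uses exactly two sibs per family and no assortative
  mating, indirect genetic effects, or genotyping error.
* The chi-square reference for QX relies on effect sizes being estimated
  without structure bias; that sensitivity is not a defect but the object of
  study, and the stratification experiments quantify it.
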