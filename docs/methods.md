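# Methods

This note documents the models implemented in `domvar`, the synthetic data
the tests run on, and the numerical and design choices a maintainer would
want to know about.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Phenotype pre-correction

Raw insemination/calving records are edited on strict bounds (heifers:
270 < age at first insemination < 900 d, NINS < 8, IFL < 365 d; cows:
550 < age at first calving < 1100 d, NINS < 8, ICF < 230 d, IFL < 365 d),
and censored records — no confirmed successful insemination — are penalised
by +21 d on IFL and +1 on NINS before any modelling.

Fixed effects are estimated with a pedigree-based sire model on the full
recorded population, `y = Xb + Z_s s (+ Z pe) + e` with
`s ~ N(0, sigma_s^2 A_s)` and, for cows, a permanent-environment effect
across parities.  Fixed effects are herd, year-month of first insemination
(one combined categorical factor), the stage's age covariate, and parity
for cows.  The ages enter as linear covariates; the functional form is an
open choice and linear is the simplest defensible one.  Pre-corrected
phenotypes keep the genetic and residual parts: `y_hc = y - Xb` for heifers
and `y_cc = s_hat + mean_k(e_hat_k)` over a cow's parities.  The permanent
environment effect is deliberately excluded from `y_cc`.

Cow phenotypes carry reliabilities `r2 = n h2 / ((n-1) h2 + 1)` (`n` =
parities used) and residual weights `w = r2 / (1 - r2)`.  The weights are
standardized to mean one — the standardization is an open choice; mean-one
keeps `sigma_e^2` on the original scale.  Heifer phenotypes get unit
weights.  The heritabilities feeding the reliability formula are
configuration inputs (typical values 0.02-0.04 for these traits).

## Relationship matrices

* Pedigree: tabular-method numerator relationship matrix computed through
  all ancestors; inbreeding coefficients are its diagonal minus one.
* Additive genomic (VanRaden method 1): codes centred by `2p_j`,
  `G = ZZ' / sum_j 2 p_j q_j`.
* Dominance genomic: `H_ij = 1 - 2 p_j q_j` for heterozygotes and
  `-2 p_j q_j` otherwise, `D = HH' / sum_j 2 p_j q_j (1 - 2 p_j q_j)`.

Allele frequencies are observed sample frequencies (base-population
frequencies are unavailable in practice).  Missing calls are mean-imputed
in `Z` and contribute 0 to `H` — both neutral in expectation.  Monomorphic
SNPs are dropped with a warning; X-linked SNPs are excluded from `G` and
`D` but retained by QC.  Which of the two common `G` scalings the field
uses varies; method 1 (sum-of-heterozygosity denominator) is implemented.

## AI-REML

All variance-component fits go through one dense average-information REML
engine.  `V = sum_i sigma_i^2 K_i + sigma_e^2 W^{-1}` is assembled and
Cholesky-factorized directly — at the few-thousand-record scale this
package targets, dense factorization is simpler and fast enough that
sparse mixed-model equations would be over-engineering.  Updates:

* three initial EM-REML iterations, then AI steps
  `theta <- theta + AI^{-1} s` with the average-information matrix
  `AI_ij = y'P K_i P K_j P y / 2` and score
  `s_i = -(tr(P K_i) - y'P K_i P y)/2`;
* an AI candidate with components pushed out of the parameter space is
  clamped to a floor of `1e-8 Vp` (sticking to the boundary) and accepted
  only if the restricted likelihood does not decrease; otherwise one EM
  step is taken — so accepted iterations never decrease the likelihood;
* convergence: relative restricted log-likelihood change < 1e-8
  (`max_iter` 200), or three consecutive absolute changes < 1e-6, which
  catches estimates crawling along the zero boundary.  Genuine
  non-convergence is reported (`converged_ = False`), never raised —
  models with weak dominance information do fail, and downstream code
  refuses to use unconverged fits rather than crashing mid-pipeline.

Standard errors are square roots of the inverse AI matrix diagonal at the
optimum; variance proportions get first-order Taylor (delta-method) SEs
propagating the full AI covariance.  Starting values split the sample
phenotypic variance equally across components.

## Association scan

The per-SNP model fits the three genotype classes as fixed effects with a
polygenic term `u ~ N(0, sigma_g^2 A)` on the pedigree relationship
matrix.  Variance components are estimated once under the no-SNP null and
held fixed for all SNPs: after one eigendecomposition `A = U L U'` every
per-SNP generalized least squares reduces to 3x3 normal equations in the
rotated basis, which is what makes 100-replicate power studies affordable.
An `exact=True` mode re-profiles the variance ratio per SNP for spot
checks; the two agree closely for null SNPs, while at a strong causal SNP
the fixed-null approximation is mildly conservative (the exact refit
attributes less variance to the residual).

Step 1 is a 2-df Wald test of equal class means; SNPs with only two
observed classes get a 1-df test and are excluded from effect
decomposition.  Multiple testing is controlled with Storey q-values (pi0
from the cubic-smoother fit over a lambda grid of 0.05-0.95, falling back
to pi0 = 1 when unstable or when fewer than 100 p-values are available);
Benjamini-Hochberg is available as an option.  Step 2 computes `a`, `d`,
their t-tests (residual df = n - 3), `h = d/a` and the variance explained.
The phenotypic variance in the "variance explained" denominator defaults
to the sample variance of the pre-corrected phenotype — the denominator
convention is configurable because published per-SNP proportions rarely
state it.

## Synthetic data

The generator produces the study conditions the package is tested under:

* **Pedigree** — discrete generations, every female of a generation mated
  to a randomly drawn sire from the active pool, 4 offspring per dam,
  sexes split exactly in half; 380 founders and 4 generations give a
  terminal cohort of 3,040 females (~11,800 animals in total).  The
  generic generator defaults to 25 sires per generation; the power-study
  design uses 80, i.e. ~38 genotyped daughters per paternal half-sib
  family, the scale of progeny-test families (a narrower pool exaggerates
  drift and family clustering of rare genotype classes beyond what a
  national genotyped cohort shows).  The pedigree does not emulate
  selection, overlapping generations or a 28-generation historical depth.
* **Genotypes** — gene dropping: founder alleles either i.i.d. per SNP at
  given frequencies (default; no LD) or taken from a coalescent founder
  haplotype pool and transmitted with Haldane recombination (1 cM ~ 1 Mb
  fallback when the map has no genetic positions).
* **Polygenic values** — sampled oldest to youngest: founders
  `N(0, sigma_u^2)`; one known parent `N(a/2, (3/4 - F/4) sigma_u^2)`;
  two known parents
  `N((a_s + a_d)/2, (1/4 (1 - F_s) + 1/4 (1 - F_d)) sigma_u^2)`, with `F`
  the parents' inbreeding coefficients.
* **QTN effects** — `a` solves `2p(1-p) a^2 = f sigma_u^2` with `f` the
  QTN variance fraction (0.05 "small", 0.10 "large") and `d = h a`.  The
  `(1-2p)d` cross-term is deliberately excluded from the scaling (the
  convention is the simplest reading of "additive QTN variance" and is
  what the power results are calibrated under).  Genotypic values are
  `+a` for the **major**-allele homozygote, `h a` for heterozygotes and
  `-a` for the minor-allele homozygote.  The attachment matters only for
  the 2-df gate (the dominance contrast is labelling-invariant); the
  major-allele convention is the one under which maximal power occurs at
  `h = -1` and minimal at `h = +0.5`, the qualitative pattern this design
  reproduces (`orient="alt"` attaches `+a` to the second map allele
  instead).
* **Phenotypes** — polygenic + QTN values + `N(0, sigma_e^2)` residual;
  defaults `sigma_u^2 = 1`, `sigma_e^2 = 19` give heritability 0.05,
  mimicking fertility traits.
* **Fertility records** — gamma-distributed day-count traits matched to
  typical heifer/cow means and SDs (heifer IFL ~30 d, cow ICF ~50 d),
  `1 + Poisson` insemination counts, herd and year-month effects, 15%
  censoring.  These tables exercise the editing/pre-correction pipeline;
  they do not model voluntary waiting periods, seasonality or culling.

## The power study

Fixed design per study: the 3,040-female cohort, one 43 Mb chromosome of
~1,260 SNPs, three QTN chosen from the panel nearest in frequency to MAF
0.43/0.19/0.09 around positions 10.1/20.1/30.0 Mb.  Each replicate draws
new polygenic values, QTN phenotypes and residuals; genotypes, pedigree
and the eigendecomposition of `A` are shared across replicates and
scenarios.  A QTN counts as detected when the most significant step-1 SNP
within +-1 Mb passes FDR q <= 0.10 **and** has dominance p < 0.01; power
is detections / 300 and precision the mean distance of the detected SNP
from the QTN.

Two design choices here deserve explanation:

* **Linkage disequilibrium.**  The founder haplotypes come from an msprime
  coalescent under a three-epoch cattle demography (Ne 150 until 30
  generations before the founders, 800 until 300, 3000 beyond), chosen so
  the panel reproduces published Holstein SNP50 LD decay (mean adjacent-SNP
  r^2 ~ 0.2-0.3, ~0.1 at 1 Mb).  The panel is thinned to ~1,260 SNPs by
  random site selection, preserving the irregular spacing (median ~21 kb
  with occasional near-duplicate pairs) of a real chip; even spacing would
  erase the close high-r^2 pairs that real panels carry.  LD is not
  cosmetic: the FDR step adapts its threshold to the number of small
  p-values, so tag SNPs flanking a QTN relax the step-1 gate in a way an
  LD-free panel cannot, and an LD-free design understates the power of
  the medium- and low-MAF QTN by roughly a factor of two.  The LD was
  calibrated against the published decay curve only, never against power
  outcomes.  Even so, realized power — especially for the
  large-variance, fully dominant scenario — retains visible
  design-to-design variability through the realized tag structure around
  each QTN; a synthetic panel reproduces the statistics of chip LD, not
  any particular chromosome's haplotype blocks.
* **Detection at the top SNP.**  Judging dominance significance at the
  single most significant step-1 SNP of the region (rather than at any
  SNP in a window) keeps a null scenario's false-detection rate near zero.
  The permissive any-SNP rule is available (`rule="any"`) but lets
  hundreds of partially correlated tags each roll the 1% dominance-test
  dice — with a +-5 Mb window its false-detection floor alone approaches
  0.5 per QTN, which no reported study design could have tolerated.  The
  +-1 Mb attribution window matches the sub-Mb precision a chip-density
  panel actually resolves; both window and rule are parameters.

Problem sizes used by the shipped checks: the acceptance script and the
acceptance test run the five reported scenarios at 100 replicates each on
the full 3,040 x ~1,260 design (a few minutes on one CPU); the
variance-component recovery check runs 20 replicates of the G+D model at
n = 1,000 with 1,200 SNPs, a size at which the REML sampling error is
still informative while the whole check stays within a test suite's
patience.

What passing these checks does and does not show: the generator reproduces
the statistical skeleton of a real fertility GWAS (relatedness, low
heritability, chip density, censoring) but not real-data pathologies —
genotyping error, selection-induced allele-frequency structure, true
Holstein haplotype blocks, herd-by-year confounding.  Power estimates are
conditional on the emulated LD and the detection rule; precision in
particular depends on LD structure that no synthetic panel reproduces
exactly.

## Numerical details and degenerate inputs

* Eigenvalues of relationship matrices are clipped at zero before use;
  near-singular `V` gets a tiny jitter (starting at `1e-10 Vp`) only if a
  Cholesky fails, and a `1e-6` diagonal ridge is available on genomic
  matrices.
* Monomorphic SNPs: skipped by the scan (reported, not scanned), dropped
  from G/D with a warning, and a monomorphic QTN falls back to its target
  MAF for effect sizing (warned) so a replicate never crashes.
* A zero-variance response converges to the boundary with all components
  at the floor.
* Ties in q-value ranking follow a stable sort of p-values; q-values are
  monotone by construction (cumulative minimum from the largest p).
* All randomness flows through `numpy.random.default_rng`; every public
  simulation function takes a seed, and fixed seeds reproduce outputs
  bit for bit.
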