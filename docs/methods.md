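# Methods

## Model

`snpblup` fits the SNP-effects linear mixed model

    y = Xβ + Zα + e,    α ~ N(0, W σ²_α),    e ~ N(0, R σ²_e).

Rows are individuals, columns of Z are standardized SNP genotypes, β are
fixed effects (always including an intercept), α are random SNP effects
and e residuals.  W = diag(w) holds per-SNP variance weights constrained to
mean one, so w_j is SNP j's relative contribution to genetic variance; the
model with W = I is ordinary SNP-BLUP/GBLUP.  R = diag(r) carries
per-individual residual-variance weights; r = 1 for raw or pre-adjusted
phenotypes, and for deregressed EBVs a common choice is
r_i = (1 − rel_i)/rel_i (helper `residual_weight_from_reliability`; mapping
reliabilities to r is deliberately left to the user).

Assumptions: additive biallelic effects, a diagonal W (no effect
correlations), diagonal R, and a single random genetic term.  Multi-kernel
models, pedigree blending and multi-trait fits are out of scope.

### Standardization

Columns of Z are centered by the training-set mean dosage (missing calls
mean-imputed first) and scaled to unit sample variance by default; an
`expected_hw` option scales by sqrt(2p(1−p)) instead.  Unit sample variance
was chosen because it makes mean-one weights interpretable as relative
variance shares and makes the SNP-BLUP/GBLUP equivalence exact on the
realized data.  Validation or prediction individuals are always centered
and scaled with the stored training statistics.  SNPs below the MAF filter
(default 0.01) are excluded before any weighting: the beta-density weight
diverges as p → 0 for a < 1.

### Heritability convention

With unit-variance columns and mean-one weights the genetic variance is
m·σ²_α, so the package reports h² = m·σ²_α / (m·σ²_α + σ²_e).  Under a
non-identity R this is the heritability on the scale of an individual with
r_i = 1.

## REML

Both fitting paths profile the restricted likelihood in the single ratio
λ = σ²_α/σ²_e.  After the R^{-1/2} transform, V = σ²_e (λK + I) with
K = R^{-1/2} Z W Z' R^{-1/2}, and σ²_e has a closed-form profile optimum,
leaving a 1-D maximization over log10 λ ∈ [−6, 6]: a 25-point coarse grid
(13 for the stochastic path) followed by bounded Brent refinement with
tolerance 1e-4.  The returned likelihood is never below any grid point
evaluated en route.  A lower-boundary optimum pins σ²_α to exactly 0
(reported converged with a boundary flag).  The likelihood convention is
the full restricted likelihood
−½[(n−c)·log 2π + log|V| + log|X'V⁻¹X| + y'Py] with no |X'X| term, so
values are comparable across weight choices on the same data — which is
what the beta-shape grid search maximizes.

### Exact path

`reml_direct` eigendecomposes K once (dense, guarded to n ≤ 20,000), after
which each λ evaluation is O(n).  It is the reference implementation: the
test suite holds the stochastic path to agreement with it.

### Stochastic Lanczos path

`reml_stochastic_lanczos` touches Z only through matrix–vector products.
log|λK + I| is split into two parts:

1. the top eigenpairs of K (default rank 120), computed once by matrix-free
   Lanczos (ARPACK) and summed exactly as Σ log(λd_i + 1);
2. the spectral tail, estimated by Hutchinson probing with Rademacher
   probes (default 30) deflated against the top subspace, each probe
   yielding a Lanczos–Gauss quadrature rule for the tail of tr(f(K)).

Deflation matters: the tail's log contributions are small, which collapses
the Monte-Carlo variance by orders of magnitude relative to plain
stochastic Lanczos quadrature, and is what lets 30 probes reproduce the
exact path's ĥ² to ±0.01 at the instance sizes the tests cover.  Because
the Lanczos recurrence of K does not depend on λ, one quadrature pass
serves every λ the optimizer visits; the probes are drawn once per fit
(explicit seed, default 1), making the stochastic profile smooth, the
optimum well defined, and the whole routine bitwise reproducible.  Lanczos
uses full reorthogonalization with an iteration cap of 200 per probe; a
near-zero recurrence norm signals an exact invariant subspace and stops the
probe with an exact quadrature.  H⁻¹y and H⁻¹X come from Jacobi-
preconditioned conjugate gradients (relative tolerance 1e-10).  The result
carries a Monte-Carlo standard error of the log-likelihood (half the probe
SE of the tail estimate).

## BLUP and prediction

Given variance components,

    β̂ = (X'V⁻¹X)⁻¹ X'V⁻¹y,    α̂ = σ²_α W Z' V⁻¹ (y − Xβ̂),

solved via Cholesky below n = 5,000 and Jacobi-preconditioned CG (relative
residual 1e-8) above; V⁻¹ is never formed.  GEBVs are Z_new α̂ with Z_new
standardized by training statistics; fixed-effect contributions are
excluded from GEBVs by default (they are not breeding values), with the
fixed-SNP contribution recoverable on request.  Effects are reported both
on the standardized scale and per allele (α̂_j / scale_j) with an explicit
effect allele (PLINK A1).

`select_fixed_snps` runs a single-marker scan (each standardized SNP
regressed on y together with X) and returns SNPs passing Bonferroni 0.05
over m tests — the default policy, chosen because no sharper threshold is
canonical; selecting n/10 or more SNPs is refused as overparameterized.

## SNP weighting

- MAF scheme: w_j = C·p_j^(a−1)(1−p_j)^(b−1) with p_j the minor allele
  frequency; a = b = 1 is unweighted, a = b = 2 matches the common
  2p(1−p) contribution assumption, a < 1 ≤ b up-weights rare variants.
- Window scheme: w_j = C·mean(α̂²_k, k in the 2S+1-SNP window centered on
  j), with α̂ from a prior identity-weight fit.  Windows are truncated at
  chromosome ends and divided by the actual SNP count (a mean, not a fixed
  2S+1 denominator) to avoid systematically down-weighting chromosome ends,
  and never span chromosomes, since LD does not.  A SNP whose window has
  exactly zero estimated effects gets weight 0 (an optional floor re-raises
  it).
- Combined scheme: the product of the two raw factors with a single
  rescale.

C always rescales to mean(w) = 1 (enforced to 1e-10).  The beta shape is
restricted to a = b and chosen by grid search (default grid
{0.5, 1, 1.5, 2, 2.5}; a finer {1, 1.25, 1.5, 1.75, 2} is provided),
refitting REML at every grid point with identical convergence settings;
ties break toward the shape nearest 1 (the unweighted model).

The two-pass protocol (`fit_two_pass`) fits round 0 with W = I, computes
window or combined weights from its α̂², and refits REML and BLUP — one
reweighting round by default; additional rounds chain the same step.
Variance components are re-estimated in every round (a flag can freeze
them).  Round 0 of a two-pass fit doubles as the unweighted reference,
which the paired validation comparisons exploit.

## Validation protocol

Repeated random sub-sampling (default 80% training, 20 replicates) and
k-fold CV (folds from one random permutation, contiguous chunks, sizes
differing by at most 1).  Predictive ability is the Pearson correlation
between GEBVs and the validation individuals' phenotypes, used directly
(no reliability weighting of r; phenotypes are assumed pre-adjusted).
Every training computation — MAF filter, standardization statistics, grid
search, weight estimation, REML, BLUP — sees only training individuals;
the test suite verifies that perturbing validation phenotypes leaves all
training artifacts bitwise unchanged.  A replicate with constant GEBVs
(e.g. σ²_α estimated 0) records r as missing with a warning.  For folds
too small for a per-fold correlation (leave-one-out), the pooled
out-of-fold correlation is reported.

## Synthetic data

The generator emulates strongly LD-structured SNP-chip data at desk scale.
Per chromosome, allele frequencies follow a reflected random walk on the
logit scale (step SD 0.03) inside `maf_range`, so neighboring SNPs have
similar frequencies, as under real LD.  Each individual carries two
haplotypes from a first-order Markov chain whose transitions preserve each
SNP's marginal frequency exactly and give adjacent alleles Pearson
correlation `ld_rho` wherever the binary Fréchet bound allows (the slowly
varying frequencies make clipping rare); `ld_rho = 0.965` reproduces a
mean adjacent-haplotype correlation of 0.965 ± 0.02 empirically.

Defaults are the study design used throughout: 2,000 individuals, 5,000
SNPs on 10 chromosomes, `ld_rho` 0.965, MAF in (0.05, 0.5), 500 QTLs with
standard-normal effects on standardized genotypes (so rarer QTLs have
larger per-allele effects; a `per_allele` option switches the convention,
making contributions ∝ 2p(1−p)), and target h² 0.3.  Residual variance is
scaled from the realized sample variance of the true breeding values, so
the target heritability is hit exactly in expectation per dataset.

What the generator does not emulate: pedigree and family structure,
selection, genotyping error, recombination hotspots, or population-scale
allele-frequency spectra.  Passing tests on this generator therefore
demonstrate correctness of the estimator and protocol under a clean
polygenic architecture with strong local LD — not robustness to the
confounding structure of real breeding populations.

## Problem sizes in the test suite

The suite runs the full protocol at reduced scale chosen as the package's
own desk-scale design: heritability recovery at n = 2,000 × m = 5,000 over
10 seeds; stochastic-vs-exact agreement on 20 random instances with
n ∈ [300, 500], m ∈ [800, 2000] and random W and R; the sparse-architecture
comparison (10 QTLs, h² = 0.5 — "large-effect" in the sense that each QTL
carries 5% of phenotypic variance) over 20 paired 80/20 replicates at
n = 1,000 × m = 2,000 with window S = 20.

## Known limitations

- The dense path's n ≤ 20,000 guard and the dense-BLUP threshold at
  n = 5,000 are conservative; the stochastic path has no such guard but its
  accuracy contract has only been verified at the sizes above.
- Window weighting assumes SNPs are in genomic order (validated at load).
- Grid search refits K per shape value; there is no low-rank update
  shortcut.
- Binary traits, dominance/epistasis and genotype dosages (non-integer)
  are unsupported.
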