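# Methods

## The model

A phenotype vector `Y` over `n` individuals is modeled as multivariate
normal,

    Y ~ N(Xb, V),     V = sum_c sigma2_c K_c + sigma2_e I,

where `X` holds fixed-effect covariates (always including an intercept),
the `K_c` are n x n genetic relationship matrices, and the variance
parameters are estimated by restricted maximum likelihood (REML).  For a
phenotype standardized to unit variance, the proportion
`sigma2_c / (sum_c sigma2_c + sigma2_e)` attached to a kinship matrix is a
heritability: the fraction of phenotypic variance tracked by that
relatedness structure.

Four relationship matrices are supported.

* **K_IBS** (standardized identity-by-state).  Off-diagonal entry (j,k) is
  `(1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))` over N
  SNPs with genotype codes `x` in {0,1,2} and in-sample allele frequencies
  `p_i`; the diagonal is `1 + F_j` with `F_j` the inbreeding-coefficient
  estimate `(1/N) sum_i (x^2 - (1 + 2p) x + 2 p^2) / (2 p (1 - p))`.
  Frequencies are always recomputed on the analyzed sample (also after
  subsetting), monomorphic SNPs are an error, and missing genotypes are
  excluded from frequency estimation and mean-imputed (centered score 0)
  in the cross-products.
* **K_IBS>t** — K_IBS with every off-diagonal entry at or below a
  threshold `t` set to zero; the diagonal is never changed.  Default
  `t = 0.05`, which is far above the per-entry sampling noise of a dense
  chip (sd about `1/sqrt(N)`), so only close relatives survive.  The
  boundary is implemented as `<= t` so that `t = 0` removes the
  numerically mean-zero distant entries.
* **K_IBD** — realized genome-sharing fractions.  Entry (j,k) counts the
  shared fraction of the four haplotype pairings (sharing one of two
  haplotypes at a site contributes 1/2, sharing both contributes 1), so
  full siblings average 0.5.  The diagonal is `1 + f_j` where `f_j` is the
  fraction of the genome shared between the individual's maternal and
  paternal copies.
* **K_IBD2** — the fraction of the genome where both chromosomes are
  shared (0.25 expected for full siblings, 0 for parent-offspring);
  diagonal fixed at 1.

IBS-type matrices are mean-centered on the off-diagonal (grand mean
subtracted; the diagonal untouched) before fitting; IBD-type matrices are
left on their absolute scale.  Centering is applied after thresholding for
K_IBS>t.  Because the intercept is always in `X`, REML projects out the
rank-one component a constant off-diagonal shift introduces, so centering
is close to a no-op for the likelihood; it is kept as the fitting
convention and exposed as a switch.

## Estimators

* **h2 from K_IBD or K_IBS>t** — single-component fit; consistent for the
  narrow-sense heritability when close relatives are present, because
  phenotypic resemblance between close relatives tracks their total
  genome sharing, not only the genotyped sites.
* **h2_g from K_IBS on unrelated individuals** — the classical
  SNP-heritability estimate (the distant tail of IBS carries information
  only about variants in LD with the panel).
* **Joint model (K_IBS>t + K_IBS, or K_IBD + K_IBS)** — two genetic
  components fitted together.  The parameter on the full IBS matrix is
  h2_g; the sum of both genetic proportions is the total narrow-sense h2.
  This uses all individuals without pruning relatives.  On a single-class
  cohort the unthresholded K_IBS single-component estimate falls between
  h2_g and h2 (its close-pair entries estimate IBD well, but its sampling
  variation is driven by the genotyped SNPs), which is the motivation for
  splitting the matrix.
* **ADE-style model (K_IBD + K_IBD2)** — the IBD2 parameter absorbs
  shared environment, dominance and epistasis collectively
  ("dominance-like").  Significance is a 1-degree-of-freedom
  likelihood-ratio test against the K_IBD-only model, with the statistic
  clamped at zero.  Because the tested variance sits on the boundary of
  its space, the plain chi-square reference (the default) is conservative;
  a 50:50 boundary-mixture reference is available as an option.
  Identifiability requires at least two relationship classes with
  different IBD2/IBD ratios (e.g. siblings and parent-offspring): with one
  class the two matrices span the same covariance family and the LRT
  statistic is identically zero.
* **Liability conversion** — for a 0/1 trait fitted on the observed scale,
  `h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))]` with population
  prevalence `K`, in-sample case fraction `P`, and `z` the standard normal
  density at the upper-`K` threshold.  The second factor corrects
  case-control ascertainment and is 1 at `P = K`.  Estimates from cohorts
  that also ascertain affected relatives remain upper bounds; no
  correction exists for that, and reports from family-leaning models are
  flagged accordingly.  The conversion is applied cohort-wide (one `P` for
  all components of a joint fit).
* **Relationship-class estimator** — for pairs of one class, heritability
  is the Pearson pair correlation divided by the class's expected IBD
  fraction (siblings and parent-offspring 0.5, half-siblings /
  grandparent-grandchild / avuncular 0.25, first cousins 0.125, MZ twins
  1).  Pairs enter once in each order so the estimate ignores member
  labeling; no per-trait standard error is defined (pairs overlap through
  the wider pedigree), but cross-trait means, 95% CIs and Wald tests on
  per-trait differences (`se = sd / sqrt(n_traits)`) are provided.
  Maternal and paternal half-siblings are pooled.  Study-style minimum
  pair counts are configurable warnings, not errors.

## REML optimizer

Average-information (AI) REML with safeguards:

* restricted log-likelihood `-1/2 [log|V| + log|X'V^-1X| + y'Py]`,
  score `-1/2 [tr(P K_c) - y'P K_c P y]`, average information
  `1/2 y'P K_c P K_d P y`;
* start at `sigma2 = var(y)/(C+1)` for all components, one EM-REML step,
  then AI steps with step-halving (likelihood-only evaluations via
  Cholesky solves; the full projection matrix is formed once per accepted
  step); EM fallback when no halved AI step improves the likelihood;
* non-negativity constraint (default) with a floor of `1e-6 * var(y)`; an
  active-set rule freezes parameters pinned at the floor whose score
  points outward and solves the AI system on the free set, which restores
  fast convergence on boundary optima; an unconstrained mode exists
  because bounded fits distort LRT nulls;
* convergence when the relative log-likelihood change drops below
  `tol = 1e-6` (or the scaled parameter change below 1e-8); `max_iter =
  100`; non-convergence returns a flagged fit, not an exception;
* standard errors from the inverse AI matrix at the optimum; proportions
  and their standard errors by the delta method with the full
  variance-component covariance; fixed effects are the GLS solution at
  the optimum.

Nested fits whose full-model likelihood lands below the null (a local
optimum) are retried from the null solution before the LRT is computed.

## The synthetic-genotype simulator

The generator emulates the reference validation design: haplotype pairs
drawn Bernoulli(`p_i`) with `p_i ~ U(0.05, 0.5)` for 5,000 observed SNPs
(the genotyping platform) and 5,000 unobserved SNPs (variants not in LD
with it); 700 individual pairs sharing 50% of the genome; an additive
phenotype `y = sum_i alpha_i z_i + e` over standardized genotypes `z` with
`alpha = sqrt(0.25/5000) = sqrt(0.5/10000)` per SNP set and
`e ~ N(0, 0.5)` — variance ~1, heritability 50%, half from observed SNPs.

Pairwise sharing copies the first member's haplotypes onto the second at a
uniformly random subset of positions: both haplotypes at an `ibd2`
fraction and one haplotype at a disjoint `2 (ibd - ibd2)` fraction, so the
expected standardized-IBS entry equals `ibd` and the both-chromosome
fraction equals `ibd2`.  By default `ibd2 = ibd` (both haplotypes copied
everywhere selected), which matches labeling pair relatedness directly by
the copied fraction; sib-realistic pairs use `(0.5, 0.25)` and
parent-offspring pairs `(0.5, 0)`.  Copied counts are `floor(x * m)`, so
recorded sharing fractions are exact.  Copied positions are an
independent subset per pair rather than contiguous segments; positions,
not blocks, are what the relatedness expectation depends on.

Optional non-additive components: `dominance_var` draws a pair component
whose covariance matrix is exactly `dominance_var * K_IBD2`, and
`shared_pair_var` adds one identical draw to both members of every
IBD2-sharing pair (a common-family-environment surrogate whose pair
covariance equals its variance).  Residual noise shrinks so the total
variance stays ~1.

What the simulator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra, contiguous IBD segments from real
meioses, pedigree-consistent sharing across more than pairs, population
structure, and case ascertainment.  Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to those real-data features; the split-chromosome
mode (causal variants every `spacing` SNPs along even chromosomes for the
observed set and odd chromosomes for the unobserved set, effects on raw
allele counts, true heritabilities from realized genotypic variances) is
the hook for re-running the same checks on any real genotype matrix.

All randomness flows from a single integer seed; replicate seeds are
`seed + replicate_index`.

## Validation scale and numerical choices

The acceptance suite regenerates the reference designs at their stated
size (1,400 individuals, 5,000 + 5,000 SNPs) with 20 replicates per shared
bank in the test suite and 50 replicates in `scripts/acceptance.py`;
Monte-Carlo standard errors are computed from the replicates actually
run.  The ADE null calibration runs 100 replicates at n = 700 (175
sib-realistic plus 175 parent-offspring pairs).  The REML oracle check
compares fitted optima against a dense grid search (0.005 resolution over
`[0, 1.5]^2`) evaluated through the error-contrast eigendecomposition — a
code path the optimizer never uses — and the analytic score against
central finite differences.  The liability conversion is checked against
numeric integration of the threshold model.

Tie-breaks and degenerate inputs: thresholding zeroes entries equal to
`t`; pruning keeps the earlier-ordered member of a related pair; traits
with only {0,1} values are treated as dichotomous and left unstandardized;
an ADE fit with no IBD2-sharing pair warns and pins the dominance-like
component at zero; `estimate_prevalence` requires at least one case and
one control.

## Known limitations

* Heritability estimates from family-heavy designs absorb shared
  environment; the ADE decomposition separates an IBD2-loading aggregate,
  not dominance specifically.
* The liability conversion assumes the normal threshold model and random
  case-control ascertainment; family ascertainment is flagged, not
  corrected.
* Dense matrix algebra throughout: fits are O(n^3) per iteration and
  memory O(n^2), comfortable to a few thousand individuals, not for
  biobank scale.
* The GRM binary format is the 4-byte-real GCTA dialect; kinship kind
  metadata travels in a sidecar `.grm.kind` text file that other tools
  ignore.
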