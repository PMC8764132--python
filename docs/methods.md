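# Methods

## Model and estimator

`scoregc` fits the bivariate variance-component model for a pair of traits
measured on partially overlapping cohorts.  Genotypes are standardized per
SNP within each cohort (mean 0, variance 1 over non-missing calls; missing
calls are mean-imputed, i.e. standardized to 0).  Phenotypes are first
residualized on their covariates plus an intercept and scaled to unit
variance, so all variance components are reported on the standardized-trait
scale and the total phenotypic variance is 1 by construction.

The method-of-moments normal equations couple the genetic covariance γg with
the environmental covariance γe carried by overlapping individuals:

    [ tr(K_A K_Aᵀ)  tr(K_C) ] (γg, γe)ᵀ = ( y₁ᵀK_A y₂ ,  y₁ᵀC y₂ )ᵀ

with K_A = X₁X₂ᵀ/M and C the partial-permutation overlap indicator; each
trait's (σ²g, σ²e) solves the analogous single-trait system with
coefficients [[tr(K²), tr(K)], [tr(K), N]].  The genetic correlation is the
unclamped plug-in ratio ρ̂g = γ̂g/√(σ̂²g₁σ̂²g₂).  When either genetic
variance estimate is non-positive, ρ̂g is reported as undefined rather than
truncated — clamping would bias the Monte-Carlo calibration checks.

With no overlapping samples the 2×2 system degenerates: γ̂g reduces to
y₁ᵀK_A y₂ / tr(K_A K_Aᵀ) and γe is structurally unidentifiable (reported as
NaN, not 0).

## Randomized traces

tr(K_A K_Aᵀ) and tr(K²) are estimated by the Hutchinson sketch
L_B = (1/B)(1/M²)Σ_b‖X₁X₂ᵀz_b‖², which is unbiased for any sketch
distribution with zero mean and identity covariance.  Defaults: B = 10
standard-normal vectors (a Rademacher option is provided; it has lower
variance for trace estimation), seeded generator.  All other entries of the
normal equations are computed exactly in the same streaming pass.

Two deliberate sketch-coherence choices:

* **One sketch per cohort side.**  The cross trace and trait 2's tr(K²)
  share the cohort-2 sketch; trait 1 shares it too when both traits sit on
  the same operator.  All moment systems then share their coefficient
  matrix when the cohorts are identical, so the randomized estimator
  reproduces the closed-form complete-overlap estimator *exactly* at any B,
  and self-correlation (y₂ ≡ ±y₁) comes out exactly ±1.
* **Canonical orientation.**  L_B is not symmetric in the two traits, so the
  pair-statistics routine canonicalises trait order by an order-independent
  content hash of the two cohorts before drawing sketches.  ρ̂g is therefore
  exactly invariant under swapping the traits.

The streaming operator processes SNP blocks (default width 1,000) of the raw
int8 dosage matrix, so memory is O(N·block) beyond the genotypes themselves
and no N×N or N×M dense standardized matrix is ever formed.  A sublinear
discrete-matrix multiplication backend could be slotted behind the same
interface; plain dense block products meet the package's target scales.

## Complete-overlap closed form

When both traits are measured on identical samples, the coefficient matrix
[[tr(K²), tr(K)], [tr(K), N]] is shared by the γ and both σ² systems, so its
determinant cancels from the plug-in ratio:

    ρ̂g = (N·y₁ᵀKy₂ − tr(K)·y₁ᵀy₂) /
          √[(N·y₁ᵀKy₁ − tr(K)·y₁ᵀy₁)(N·y₂ᵀKy₂ − tr(K)·y₂ᵀy₂)]

This needs only per-SNP scalars (two operator applications per trait), no
randomization, and by Cauchy–Schwarz the shared determinant is positive, so
a non-positive denominator factor coincides exactly with a non-positive
genetic variance estimate.  It is validated against the exact-MoM plug-in
oracle rather than derived from an external reference.  `fit(method="auto")`
selects it whenever the two cohorts are the same panel rows.

## Inference

Every moment statistic decomposes additively over contiguous SNP blocks
(the sketch images X₁X₂ᵀZ are cached per block as N-vectors), so a
delete-one block jackknife (default g = 100 blocks) re-solves all systems
per leave-out without re-reading genotypes.  The SE of ρ̂g is jackknifed
directly on the ratio — not via a delta method — because the decomposition
makes full recomputation cheap.  The jackknife unit is SNP blocks, chosen
because the estimator's randomness over architectures enters through which
SNPs carry effects; blocks of individuals would not decompose the sketch
caches.  The null test is the two-tailed Wald test z = ρ̂g/SE against a
standard normal.  The CLI applies a Bonferroni flag across the pairs in the
run.

## Quality control

Markers are filtered in a fixed order — missingness > 1%, minor allele
frequency < 1%, Hardy–Weinberg 1-df chi-square p < 1e-7, zero variance —
with each dropped SNP attributed to the first failing filter, making the QC
report deterministic.  The chi-square test (rather than the exact test) is
cheap and adequate at the extreme 1e-7 threshold; this is a documented
deviation knob.  A BED-style region-exclusion option supports masking
regions of long-range LD such as the MHC; no default coordinates are baked
in.  When the two cohorts sit on different panels, a SNP must survive QC in
both panels to be retained, so M is common as the model requires.

## Simulator

The generator emulates the study conditions the estimator is validated
under:

* **Genotypes**: per-SNP allele frequency uniform on [0.05, 0.5] (tests) and
  binomial(2, f) dosages, independent across SNPs — linkage equilibrium.
* **Effects**: per-SNP causal status from a four-component mixture —
  infinitesimal (1, 0, 0, 0); medium polygenicity (0.1, 0.2, 0.2, 0.5); low
  polygenicity (0.01, 0.05, 0.05, 0.89) for ([1,1], [1,0], [0,1], [0,0]).
  Effect variance per causal SNP is h²t/(q_t·M) with q_t the per-trait
  causal probability (so the expected total genetic variance is exactly
  h²t, matching denominators 0.3M and 0.06M for the two polygenic
  mixtures); shared-causal effects are bivariate normal with correlation
  equal to the ρ parameter.
* **Traits**: y = Xβ + ε with environmental variance 1 − h² (unit trait
  variance in expectation) and environmental correlation only across
  overlapping individuals.  Overlap assigns the first ⌊φN⌋ panel
  individuals to both cohorts.  Binary traits threshold the realized
  liability at its empirical upper quantile so case counts are exact in
  finite samples.
* **Ground truth**: each replicate records the realized genome-wide
  ρg = Σβ₁β₂/√(Σβ₁²Σβ₂²) from the drawn effects.  Under the infinitesimal
  architecture its expectation equals the ρ parameter; under the mixtures it
  shrinks by P([1,1])/√(q₁q₂), and the recorded realized value — not a
  nominal constant — is the reference for bias assessment.

What the simulator does **not** emulate: linkage disequilibrium, population
structure or relatedness, case ascertainment, and covariate effects.
Passing tests therefore demonstrate unbiasedness, calibration and the
algebraic identities under linkage equilibrium; in real data with LD the
point estimates remain method-of-moments consistent for the model's
parameters, but standard-error constants differ.

## Numerical choices

* 2×2 systems are solved in closed form; a system whose determinant is below
  1e-12 relative to its squared scale raises a conditioning error (inside
  the jackknife this degrades to a NaN leave-out value and hence a NaN SE,
  never a silent answer).
* Sketches, effect draws and genotype draws all flow through seeded
  numpy Generators; a fit is a deterministic function of
  (data, B, n_blocks, seed).
* Jackknife SE returns exactly 0 when all leave-one-out values are
  identical, and NaN (not a partial answer) if any leave-out is undefined.
* Binary traits are analyzed on the observed 0/1 scale; the pipeline warns
  when prevalence < 0.5%, where observed-scale estimates become noisy.
  Liability-scale transformation is out of scope.

## Validation scales

The test suite and the acceptance script size their simulations for a
single desktop CPU: null calibration uses N = 2,000 individuals and
M = 5,000 SNPs with 100 replicates per architecture; recovery checks use
N = 1,200–5,000 and M = 2,000–5,000 with 50–100 replicates; jackknife
calibration uses N = 1,000, M = 2,000 with 200 null replicates per
heritability setting.  All Monte-Carlo assertions use 3-standard-error
tolerances computed from the replicates themselves, and binomial tolerances
for rate checks — tolerances are never hand-tuned constants.

## Known limitations

* Genotypes are simulated in linkage equilibrium; SE magnitudes on real,
  LD-structured data will differ even though unbiasedness and calibration
  carry over.
* The environmental covariance γe is identifiable only through overlapping
  samples; with zero overlap it is reported undefined.
* The complete-overlap estimator reports only ρ̂g and its uncertainty; the
  variance components shown alongside it come from the randomized
  single-trait solver.
* No relatedness handling: the user supplies unrelated samples.  PLINK 2,
  VCF/BGEN and dosage genotypes are not read.
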