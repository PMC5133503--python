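# Methods

## Model

`longvc` fits Gaussian variance-component models to a quantitative
trait measured at k visits on n individuals in extended pedigrees. With
visit-major stacking (all individuals at visit 1, then visit 2, …), the
covariance of the stacked trait vector is

    Ω = G ⊗ 2Φ + E ⊗ I_n [+ s sᵀ ⊗ K]

* **Φ** — theoretical kinship, computed by the recursive tabular method
  over a topological order of each pedigree: founders have φ = ½ on the
  diagonal and 0 off it; a non-founder i has
  φ(i,i) = ½ + ½·φ(father, mother) and
  φ(i,j) = ½·(φ(father,j) + φ(mother,j)) for earlier j. The recursion
  is exact, O(n²), and handles inbreeding loops (the pedigrees of the
  emulated study are not documented as inbred, but nothing precludes
  it, so loops are supported).
* **G, E** — k×k genetic and environmental visit covariance matrices.
* **K** — optional region-local empirical kinship (standardized
  VanRaden-type GRM, Z Zᵀ/m with dosages centered at 2p and scaled by
  √(2p(1−p))). The visit loadings s make the gene-specific component
  rank-1 across visits: the "constrained" kernel model forces all
  loadings equal (one parameter, σ²_geff = s²), the "unconstrained"
  model frees them. The rank-1 form was chosen over independent
  per-visit components because it nests the constrained model, so the
  likelihood-nesting invariant holds for the kernel models too. An
  allele-sharing kernel ((g−1)(g−1)ᵀ/m) is available behind a flag.

The mean model has per-visit intercepts and covariate coefficients,
plus the SNV dosage with its coefficient shared across visits
(constrained test), free per visit (unconstrained test), or absent
(null). Age is centered before interactions are formed; sex and
smoking are 0/1 indicators (sex = 1 for female).

Estimation is full maximum likelihood (not REML), so likelihood-ratio
tests between nested mean models are valid: the constrained test has
1 df, the unconstrained k df, the averaged-trait univariate test 1 df.
A variance component tested at the boundary (σ²_geff = 0) uses the
½:½ mixture of a point mass at zero and χ²₁; a statistic of exactly
zero is reported as p = 1 so boundary fits are never suggestive. For
the k-loading kernel model the exact simultaneous-boundary mixture is
analytically messy and the full χ²_k tail is used instead, which is
conservative.

## Estimation

Mean parameters are profiled out by generalized least squares at every
covariance evaluation, so the optimizer (L-BFGS-B) works only on
covariance parameters. G and E are parameterized through log-Cholesky
factors (log diagonal, free sub-diagonal), which keeps them positive
semidefinite by construction and lets variances reach the boundary as
the log-diagonal floor (−8, i.e. variance ~1e−7) — this was preferred
over a per-correlation atanh parameterization, which cannot guarantee
a positive-definite correlation matrix for k ≥ 3. Boundary solutions
are flagged.

Two evaluation paths produce identical likelihoods and both carry
analytic gradients:

* **complete data, no kernel** — eigendecompose 2Φ once per pedigree
  block; in the rotated basis the problem factors into n independent
  k×k Gaussian problems, evaluated batched. A dedicated scalar
  implementation handles k = 1.
* **missing visits and/or kernel present** — dense per-pedigree
  covariance blocks with Cholesky solves; missing (individual, visit)
  cells are deleted from the stacked system (an MAR assumption),
  rather than dropping whole individuals.

Ω is block-diagonal by pedigree throughout; unrelated singletons are
merged into one diagonal block. Gradients use the envelope theorem
(the profiled GLS optimum zeroes the mean-parameter derivative) and
were verified against central differences to ~1e−8. Convergence is
declared at relative tolerance 1e−11 on the objective; alternative fits
are warm-started from the null fit's covariance parameters, which both
speeds them up and makes the nesting
logL_unconstrained ≥ logL_constrained ≥ logL_null structural (an
optimizer started at the null optimum cannot end below it). On
convergence failure the fit restarts from moment-based initials at
heritability guesses 0.4/0.15/0.55; non-convergence is flagged in the
result, never raised.

Missing dosages are mean-imputed (2·ALT frequency) at test time;
listwise deletion is available. Monomorphic variants yield a flagged
p = 1 result rather than an exception. Threshold tallies use strict
`p < threshold`, the conservative reading of "meeting a threshold".

The covariate screen is marginal — each candidate (centered age, sex,
age×sex, age², age²×sex, smoking) is tested one at a time as a fixed
effect in the polygenic model of the time-averaged trait and carried
forward at p < 0.05 — matching the convention of pedigree VC software
rather than a joint screen.

## Gene-centric tests and the dense kernel

The empirical kernel couples individuals across families, which
matters for power: within a family the *expectation* of the empirical
kinship built from gene-dropped variants equals the pedigree kinship,
E[K] = 2Φ, so the within-family part of K is nearly collinear with the
polygenic component. Much of the identifiable regional signal — the
departure of K from 2Φ — therefore lives in the cross-family entries.
`longvc` models the full dense kernel by default, exactly and cheaply,
by exploiting its low rank: K = Z Zᵀ with Z the n×m standardized
scores, so with U = s ⊗ Z and block-diagonal A = G⊗2Φ + E⊗I the
matrix inversion lemma gives

    Ω⁻¹ = A⁻¹ − A⁻¹U (I_m + UᵀA⁻¹U)⁻¹ UᵀA⁻¹

and every solve stays per-pedigree plus an m×m capacitance system.
This path is verified in the test suite against a brute-force dense
covariance fit (identical likelihoods) and against central-difference
gradients. A `block_by_pedigree=True` option zeroes cross-family
kernel entries (cheaper; identical null calibration; less power).

## Synthetic data generator

The generator emulates a large family-based longitudinal
blood-pressure study: **20 extended pedigrees, 849 individuals** over
3–4 generations, **three visits** of an SBP-like trait, age/sex/smoking
covariates, and biallelic SNVs gene-dropped through the pedigrees
(founder alleles Bernoulli(MAF), Mendelian transmission; variants are
independent — no linkage-disequilibrium structure). Pedigree shapes
are random but the total size is exact; married-in spouses enter as
founders.

The trait model is y_it = μ_t + Σ_c β_c g_ic + covariates + a_it + e_it
with polygenic covariance G ⊗ 2Φ and environmental covariance E ⊗ I.
Defaults, chosen to be realistic for an adult blood-pressure cohort
(units: the within-visit genetic-plus-environmental trait variance is
1):

| parameter | default | meaning |
|---|---|---|
| h² | 0.40 | polygenic heritability per visit |
| ρ_g | 1.0 | genetic correlation across visits (time-stable effects) |
| ρ_e | 0.4 | environmental correlation across visits |
| causal fractions | 0.0278 … 0.0017 (nine variants, MAF 0.2) | variance fraction per SNV |
| null variants | 20, MAF ~ U(0.05, 0.5) | known-zero-effect markers |
| age | N(45, 12²) at baseline, +5 y per visit, slope 0.02/y | |
| sex difference | 0.3 SD | female − male |
| smoking | prevalence 0.2, effect 0.2 SD | |

A variant with MAF p configured to explain fraction V of variance gets
β = √(V / (2p(1−p))). The nine default fractions are read as
*proportions* of variance (0.0278 = 2.78 %); the alternative
percentage reading (0.0278 %) would make every variant undetectable at
any realistic sample size, so proportions are the only self-consistent
interpretation. ρ_g defaults to 1 because the emulated study's
generating model has stable genetic effects across time — the regime
in which constraining β is the right choice; lowering ρ_g is the
natural experiment for where the constrained test should lose power.

Genotypes are generated once per study and phenotypes re-simulated per
replicate (mirroring a study with fixed measured genotypes);
per-replicate seeds derive from the master seed by
`SeedSequence.spawn`, so replicates are independent and individually
re-runnable, and identical seeds give byte-identical output.

What the generator does **not** emulate: linkage disequilibrium,
ascertainment, medication use or secular trends, non-Gaussian trait
tails, genotyping error, and visit-level covariate drift beyond the
fixed age increment. Calibration and power results on these synthetic
data therefore demonstrate correctness of the statistics under the
stated model, not robustness to those real-data features.

## Study sizes used by the test suite and acceptance script

Monte-Carlo studies run at the default 849-individual design: 500
phenotype replicates for null calibration in the test suite (200 in
the acceptance script, which also re-runs power and recovery), 200
replicates for power comparisons, 100 for parameter recovery, 10⁵
gene drops for the kinship oracle, 100 random small instances for the
likelihood oracle. Null-calibration studies gene-drop a fresh null SNV
(and null-region variant set) in every replicate: the chi-square and
mixture nulls are statements about the tests marginally over genotype
draws, and the rejection rate conditional on a single fixed dosage
vector fluctuates around the nominal level by more than binomial
noise in family designs. The acceptance script's gene-centric power study
uses a 60-variant region with 4 causal variants jointly explaining 5 %
of trait variance, 50 replicates. Binomial 95 % intervals around the
nominal level are the acceptance bands for calibration rates.

## Known limitations

* ML (not REML) variance estimates carry the usual small downward
  bias, visible as a ĥ² bias of order p/n (~1–2 % here).
* The unconstrained kernel p-value is conservative by construction.
* Standardized-GRM scaling of K is one of several possible localized
  kinship estimators; others differ by scaling and would shift
  h²_geff's scale, not the test's validity.
* The generic (kernel/missing-data) path is O(Σ(n_f k)³) per
  evaluation; very large single pedigrees would need further structure
  exploitation.
* The averaged-trait test averages whatever visits are observed; with
  informative missingness that average changes meaning.
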