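# Methods

## Model and test

The unit of inference is one gene × one exposure in a case–control
sample. Writing `G` for the n×p cis-genotype dosage matrix (alt-allele
dosages in [0,2]), `w` for the gene's expression weights and
`T = G w` for predicted expression, the alternative is a hierarchical
logistic model with a fixed burden interaction `β_TE (T·E)` and random
per-SNP interaction slopes `b_j ~ N(0, τ²)` on `G_j·E`. Both
components are tested by score statistics against the null logistic
fit of `Y` on `[X, E, T]`, so the alternative is never fitted.

* Fixed component: `U = c'(Y−μ̂)` with `c = T∘E`; its efficient
  variance partials out `[X, E, T]` through the working weights
  `W = μ̂(1−μ̂)`; `U²/V` is referred to χ²₁.
* Random component: `Q = ‖Z'(Y−μ̂_a)‖²` with `Z = diag(E) G`, where
  `μ̂_a` comes from the null *augmented with the fixed interaction
  column*. The augmentation projects the burden direction out of the
  variance-component score, which (a) makes the random component a
  test of genuinely residual interaction and (b) renders the two
  component p-values asymptotically independent; the component
  correlation is checked empirically in the test suite. The null law
  of `Q` is `Σ λ_k χ²₁` with `λ_k` the eigenvalues of the
  projection-adjusted covariance of `Z'(Y−μ̂_a)`.
* Combination: Fisher's product rule (closed-form χ²₄ tail) and an
  adaptive weighted combination over the grid λ ∈ {0, 0.1, …, 1.0} of
  `λu + (1−λ)v`, `u = −ln p_fixed`, `v = −ln p_random`. Each weighted
  statistic has a hypoexponential closed-form tail; the overall
  p-value of the minimum tail over the grid is calibrated by exact 2-D
  integration of the iid Exp(1) measure over the acceptance polygon
  (adaptive quadrature, absolute tolerance ~1e-10, with integration
  break points at the polygon kinks). The grid+min-p construction is
  this package's own design for an adaptive weighted combination; it
  is not claimed to replicate any specific published calibration
  scheme.

The null model deliberately contains `X`, `E` and `T` but no per-SNP
main effects: the burden term carries the gene's main effect in the
hierarchical model. `random_score_test(..., include_fixed_in_null=False)`
exposes the unprojected variant as a switch.

## Chi-square mixture tail

`mixture_tail_prob` evaluates `P(Σ λ_k χ²₁ ≥ q)` by a tiered
strategy: exact scaled-χ² when all eigenvalues are equal; Ruben's
convergent mixture-of-central-χ² series (common scale
`β = 2λminλmax/(λmin+λmax)`, truncation bounded by the unassigned
mixture mass, numba-accelerated) for spectra of ≤16 eigenvalues;
otherwise Imhof's characteristic-function inversion integral via
adaptive quadrature (absolute tolerance 1e-9). When the inversion is
unreliable (extreme tails, ill-conditioned spectra) the
Liu–Tang–Zhang moment-matching approximation is used and flagged in
the output (`davies_fallback`). p-values are floored at 1e-300.

## Logistic null fitting

The null is fitted by damped Newton/IRLS (relative step tolerance
1e-8, maximum 100 iterations, steps capped at 10 per coordinate).
Linear predictors beyond ±40 or a singular information matrix raise a
separation error. The solver is cross-checked against
`statsmodels.Logit` to 1e-6 in the unit tests; an in-package solver is
used because permutation oracles refit the null hundreds of thousands
of times.

## Expression weight training

Per gene: variants within ±500 kb of the gene boundary (clipped at
position 1, optional boolean panel mask restricting trainable
variants); GRM `K = (1/m) Z Z'` on standardized dosages; REML
heritability with the likelihood-ratio test against `σ²_g = 0`
referred to the boundary mixture `½χ²₀ + ½χ²₁`; genes with gate
`P ≥ 0.01` are excluded. REML maximizes the restricted likelihood of
`V = σ²(h² K + (1−h²) I)` by an exact one-dimensional profile search
over `h²` (Brent, tolerance 1e-8) in the eigenbasis of `K`, with `σ²`
profiled analytically — equivalent to the usual iterative
REML updates for this single-ratio model but unconditionally stable
at desk scale, and allowing the eigendecomposition to be reused
across genes on a fixed panel.

Weight schemes: `top1` (marginal OLS slope of the largest-|z|
variant), `lasso` and `enet` (elastic-net mixing 0.5, 100-value
penalty path, inner 5-fold CV; coordinate descent via scikit-learn on
standardized genotypes, coefficients back-transformed to the dosage
scale). Model selection uses pooled out-of-fold R² from seeded
5-fold CV, ties broken enet > lasso > top1. Genes passing the
heritability gate are retained even when their best CV R² is ≤ 0 (the
gate is the only exclusion rule).

## Allele harmonisation

Weights and cohort genotypes are matched on chrom:pos; exact ref/alt
matches pass, swapped alleles flip dosage `d → 2−d`, strand
complements are matched after complementing, and strand-ambiguous
(A/T, C/G) weight variants are always dropped — silent sign errors
are worse than lost variants. A gene is kept when at least one
nonzero-weight variant survives harmonisation.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, not human genetics in detail:

* **Genotypes** — two independent haplotypes per individual, each the
  indicator that a latent Gaussian with block-AR(1) correlation
  (ρ^|i−j| within a block, 0 between) falls below a MAF-matched
  quantile. MAFs are drawn uniformly from a configurable range
  (default 0.05–0.5). This gives controllable, reproducible LD with
  none of the long-range structure of real genomes.
* **Expression** — `y = G_c β_c + ε` with the noise orthogonalised
  against the genetic value and scaled so the realised variance ratio
  equals the target h² exactly. Default panel size 251, matching a
  typical single-tissue reference panel.
* **Cohorts** — disease follows the hierarchical logistic model above
  (intercept −2.2, ~10% population prevalence; study effect 0.1; age
  effect 0.01/year; defaults β_E = β_T = 0, configurable). Cases and
  controls are drawn without replacement from a simulated population
  20× the target sample, mimicking outcome-dependent sampling, so all
  calibration results hold *under ascertainment*. Five genotype PCs
  are computed from the sampled cohort (orthonormal over samples) and
  used as covariates. Random interaction slopes `b_j` are drawn once
  per gene.
* **Exposures** — a catalog of 14 recipes shaped like established
  breast-cancer risk factors: continuous variables with the standard
  per-unit codings (per 5 years, per 10 g/day, per 2 years, per
  5 kg/m², per 12 months, per 5 cm), binary and ordinal (1/2/3/4+)
  variables with realistic prevalences, and eligibility restrictions
  (reproductive factors parous-only; BMI by menopausal status; MHT
  use postmenopausal-only, with former-use flags available as extra
  covariates). Means and prevalences approximate published
  population summaries; no exact match to any real cohort is claimed.

What passing tests on these data do **not** show: robustness to real
LD (imputation-induced correlation, allele-frequency spectra),
exposure measurement error or recall bias, platform heterogeneity, or
confounding structures beyond simple study/age/PC effects.

## Calibration and power studies (problem sizes)

The repeated-simulation studies use: null calibration — 2,000
replicates of n = 2,000 ascertained samples (1,000/1,000) with one
50-SNP gene, β_E = β_T = 0.1 (odds ratios ≈ 1.1, a realistic
risk-factor scale), β_TE = τ = 0; power — 200 replicates per effect
size at β_TE ∈ {0.15, 0.30, 0.60} (with sd(T) ≈ 0.3 in this design
the largest effect is a per-SD interaction odds ratio of ≈ 1.2);
weight recovery — 50 replicates of
n = 1,000 training / 500 held-out samples, 100 variants, 10 causal,
h² = 0.5 (elastic net); heritability-gate size — 2,000 null genes on
a fixed 300-sample, 100-variant panel with the GRM eigendecomposition
reused. The reproduction script (`scripts/acceptance.py`) uses 500
null replicates, 150 power replicates, 20 recovery replicates, 1,000
gate replicates and a 60-gene null scan; these sizes are the
package's choices for a desk-scale reproduction.

## Numerical choices and degenerate inputs

* Fixed-component variance ≤ 1e-12 → degenerate-interaction error
  (constant `T∘E`).
* All eigenvalues of the score covariance below 1e-12 (absolute) or
  1e-10 relative to the largest → degenerate error; smaller
  eigenvalues are trimmed before inversion.
* Zero p-values entering combinations are clamped to 1e-300.
* Monomorphic variants are excluded from the GRM; an all-monomorphic
  gene is gated out.
* Missing exposures are handled complete-case per exposure; no
  imputation anywhere.
* Region queries on uncompressed VCFs stream the whole file and
  filter on 1-based closed coordinates; indexed queries are used when
  a tabix index is present.
* Fold assignment everywhere is a seeded shuffle; identical seeds
  give bit-identical outputs end to end.

## Known limitations

* The adaptive combination's calibration assumes exact independence
  and uniformity of the component p-values; both hold asymptotically
  by construction and are verified empirically at n = 2,000, but at
  small n (≲ a few hundred) the chi-square-mixture approximation for
  the random component shows visible finite-sample error in the body
  of its distribution, and conditional (permutation) and
  unconditional reference distributions differ at the 1–4% level on
  the p scale. Gene-level p-values from very small strata should be
  treated with caution.
* With strong main effects under case–control ascertainment the
  fixed-component score test can run slightly above nominal level in
  finite samples (heavy-tailed burden-interaction regressors); this
  is a property of the score construction, not of the
  implementation.
* The variance-component model draws `b_j` independently per SNP;
  correlated functional structures (e.g. effects proportional to LD
  scores) are not modelled.
* REML assumes Gaussian expression residuals; heavy-tailed expression
  should be rank-normalised upstream.
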