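# Methods

## Model and solver

`mmgp` fits Gaussian mixed models y = Xβ + Σᵢ Zᵢuᵢ + ε with uᵢ ~ N(0, Kᵢσ²ᵤᵢ)
and ε ~ N(0, Iσ²ₑ).  At fixed variance components the BLUEs and BLUPs solve
Henderson's equations; the implementation assembles the coefficient matrix

    C = [ X′X        X′Zᵢ                 ]
        [ Zᵢ′X   Zᵢ′Zᵢ + Kᵢ⁻¹·(σ²ₑ/σ²ᵤᵢ)  ]

on the observed rows and inverts it densely (the diagonal blocks of C⁻¹ are
returned; multiplied by σ²ₑ they are prediction-error variances, and they feed
the EM updates).  Records with missing responses are excluded from the row
space but **every random level keeps its column**, so unphenotyped levels
(unrealized crosses, untested hybrids) obtain BLUPs through their covariance
with observed levels.  This one policy implements genomic prediction; there is
no separate "predict new genotypes" code path.

Residual structure is fixed at Iσ²ₑ; correlated or heteroscedastic residuals
are out of scope.

### Restricted likelihood

All algorithms report

    ℓ_R = −½ [ log|V| + log|X′V⁻¹X| − log|X′X| + y′Py + (n−p)·log 2π ]

with V = Σ ZᵢKᵢZᵢ′σ²ᵤᵢ + Iσ²ₑ and P the REML projection.  The −log|X′X| term
makes ℓ_R invariant under reparameterizations X → XB of the same fixed-effect
space (verified by test); software that omits it differs from `mmgp` by a
data-independent constant, which cancels in likelihood ratios and information
criteria.  AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n count k = number of
variance components only — under REML the fixed effects are profiled out, and
the alternative convention of counting them too would only shift comparisons
by a constant within a fixed X.

## Variance-component estimation

Three REML algorithms share this likelihood and the non-negativity constraint
(components are clamped at 1e−10·Var(y) and flagged `boundary`; the residual
variance is kept strictly positive):

* **EMMA** (single kernel only).  With S the projection orthogonal to X, one
  eigendecomposition of S(ZKZ′+I)S reduces REML to a 1-D profile over
  δ = σ²ₑ/σ²ᵤ, scanned on a 100-point log grid over [1e−9, 1e9] and refined
  by bounded minimization between the best grid point's neighbours.
  Deterministic and non-iterative; `fit(…, method="auto")` uses it whenever
  the model has exactly one random term.  If the error contrasts are
  numerically zero (response lies in the fixed-effect space) both components
  are floored and flagged rather than optimizing a degenerate profile.
* **AI-REML** (default for ≥2 kernels).  Newton-type iteration
  θ ← θ + AI⁻¹s on the *direct* n×n V parameterization (efficient when
  covariance structures are dense), where sᵢ = −½[tr(PV̇ᵢ) − y′PV̇ᵢPy] and
  AI is the average-information matrix ½y′PV̇ᵢPV̇ⱼPy.  Steps that decrease
  ℓ_R are halved (up to 10 times), then replaced by one EM step; a singular
  AI matrix likewise falls back to one EM step (logged in the trace).
  Convergence: |Δℓ| < 1e−8 and max relative |Δθ| < 1e−6; max 100 iterations.
* **EM-REML**.  Classical fixed-point updates through the MME inverse,
  σ²ᵤᵢ ← (ûᵢ′Kᵢ⁻¹ûᵢ + σ²ₑ·tr(Kᵢ⁻¹Cⁱⁱ))/qᵢ and
  σ²ₑ ← (y′y − β̂′X′y − Σûᵢ′Zᵢ′y)/(n−p).  Monotone in ℓ_R
  (property-tested); slow near boundaries — when a true component is zero,
  EM approaches the boundary geometrically and may exhaust its iteration
  budget with a small positive value.  Max 500 iterations by default; all
  tolerances are keyword-configurable.

Initialization for the iterative algorithms splits Var(y) equally across all
components.  Estimation is fully deterministic; only the data generators and
cross-validation consume seeds.

### Numerical policies

* Structure inversion: Cholesky with escalating diagonal jitter starting at
  1e−6·mean(diag K) when the factorization fails *or* a pivot collapses below
  √1e−12 of the largest (a plain success test misses numerically singular PSD
  matrices).  VanRaden matrices computed from observed allele frequencies are
  always singular (the centred marker matrix annihilates the 1-vector), so
  this path is routine, not exceptional; the induced perturbation is O(1e−6)
  relative.
* Rank-deficient fixed designs: pivoted-QR drop of aliased columns with a
  warning.
* V not positive definite in ℓ_R: one tiny jitter retry, then an error.

## Kernels

* Additive (VanRaden): A = ZZ′/2Σpⱼqⱼ, Z centred by 2pⱼ−1.  Allele
  frequencies default to those observed in the supplied individuals
  (user-supplied frequencies accepted).  Missing genotype cells are imputed
  to the per-marker mean of the coded values before centring — the simplest
  unbiased default.  Monomorphic markers contribute zero to numerator and
  denominator and are excluded with a logged count (an error only when *all*
  markers are monomorphic).
* Dominance: W = heterozygosity(0/1) − 2pⱼqⱼ; denominator Σ2pⱼqⱼ(1−2pⱼqⱼ)
  by default (`denominator="su"`), with Σ2pⱼqⱼ available as
  `denominator="simple"` — the two conventions in circulation differ only by
  this scalar, which rescales σ²_D but not BLUP rankings.  Additive input is
  recoded ±1→0, 0→1.  A panel with no heterozygous calls has no estimable
  dominance structure and errors.
* Epistatic: Hadamard products (PSD by the Schur product theorem).
* Letter conversion: per marker the two observed alleles are identified;
  the minor allele codes +1 (frequency ties broken toward the alphabetically
  earlier allele, so conversion is deterministic); monomorphic, all-missing
  and >2-allele markers are dropped with logged warnings.

## Hybrid prediction

For a two-heterotic-group single-cross design the model carries three random
terms — GCA₁ (females, K₁), GCA₂ (males, K₂) and SCA (crosses,
K₃ = K₁⊗K₂, labels `female:male` in female-outer order, consistent with the
incidence built by `assemble`).  Hybrids are predicted as
u_GCA1[f] + u_GCA2[m] + u_SCA[f:m]; by default values are genetic values
relative to the intercept, with `include_intercept=True` adding the mean
fixed-effect contribution (the value at the average fixed level — the natural
report when locations are fixed effects).  Rank ties are broken by parent
label so output files are reproducible.

Mid-parent prediction for species without heterosis averages the parental
GEBVs over all C(n,2) unordered pairs (selfs excluded).

## Cross-validation

`kfold_cv` partitions the *observed* records into k folds **by genotype
level** when a grouping is supplied (records of one genotype never straddle a
fold boundary — stricter than record-wise CV and immune to replicate
leakage), masks one fold at a time, refits the model from scratch (variance
components included), predicts the masked records through their retained
levels, and reports the Pearson correlation of predicted vs observed per
fold.  Run r of a repeated CV derives its partition from seed+r; the
partition depends only on the sorted group labels, so results are invariant
to record order and bit-reproducible for a fixed seed (given fixed BLAS).
Folds with zero response variance, or whose training fold cannot be fitted
(e.g. a degenerate constant-response training set), are recorded as missing
with a warning.

## GWAS scan

`mm_scan` is a P3D-style mixed-model scan: the polygenic null model
y = Xβ + Zu + ε, u ~ N(0, Kσ²ᵤ) is fitted once by EMMA; data are rotated by
V^{−1/2} through the eigendecomposition of ZKZ′; each marker is then tested
as an added fixed covariate with an exact t (Wald) test in the rotated
regression.  Variance components are *not* refitted per marker — the standard
speed/accuracy trade-off, recorded in the output metadata.  With K = I (or a
null polygenic component) the rotation is a scalar and the p-values equal
ordinary-regression t-tests exactly, which anchors the implementation to a
closed form.  Monomorphic and fixed-effect-aliased markers are reported as
missing.  A Bonferroni −log₁₀ threshold accompanies raw scores; no FDR
machinery.  Diploid additive coding only; polyploid scoring is out of scope.

## Synthetic data

The generators exist to create data whose true genetic architecture is known
exactly, so recovery can be asserted sharply.

* `simulate_markers`: per-marker allele frequency uniform on `maf_range`
  (default 0.05–0.5), Hardy–Weinberg genotypes (Binomial(2,p)−1), optional
  fully-inbred panels (±1 only).  `n_families > 1` adds the population
  structure of real breeding panels: each family descends from a founder
  genotype, lines inheriting each founder marker with probability
  1 − `family_mix` (default 0.3).
* `simulate_phenotype`: standard-normal effects on `n_qtl` markers (default:
  all markers — a polygenic trait consistent with the GBLUP model being
  fitted), with the additive and dominance genetic-value columns **rescaled
  so their realized sample variances equal the requested values exactly**.
  This differs from expectation-scaled simulators on purpose: a requested
  h² = 0.5 is exact in every realized sample, which makes small-n recovery
  tests sharp.  Residual noise is drawn N(0, var_e), not rescaled.  True
  breeding/genetic values are returned for recovery checks.  One seed is
  split deterministically across QTL choice, additive effects, dominance
  effects and noise, so changing one knob leaves the other draws untouched.
* `simulate_hybrid_system`: two inbred parental panels (default 20+20 lines,
  511 markers, 4 families per group), K₁/K₂/K₃ from the kernels above,
  GCA/SCA effects drawn from N(0, K·σ²) (eigen-factorization) and rescaled
  to exact realized variances, phenotypes composed over `n_locations`
  (default 4) fixed location effects with N(0, var_e) residuals, and a
  random subset of crosses observed (default 25%, i.e. 100 of 400 in the
  default design).  Note the variance scale: inbred VanRaden kernels have
  diagonal ≈ 2 (1+F), hence K₃ diagonal ≈ 4, so a drawn effect variance v
  corresponds to a kernel-scale component σ² ≈ v/diag — REML estimates are
  on the kernel scale and tests compare accordingly.

What the generators deliberately do *not* emulate: linkage disequilibrium
along chromosomes, selection, genotyping error, multi-allelic loci and
genotype×environment interaction.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to every feature of real breeding data.

## Validation design and problem sizes

The end-to-end suite (`tests/test_acceptance.py`) checks, at sizes chosen to
keep the full suite under a few minutes on one core:

* heritability recovery: 20 replicates of n = 500, m = 1000, equal additive
  and residual variances; mean ĥ² must land in [0.45, 0.55];
* algorithm equivalence: 20 single-kernel instances (n = 100) where EMMA, AI
  and EM must agree on all components and ℓ_R to 1e−3 relative;
* oracle equivalence: the Henderson solver against an independent dense-GLS
  evaluation (1e−6 relative) and all three algorithms against the ANOVA
  closed form on balanced one-way layouts (1e−6);
* AI/EM BLUP agreement on the 20×20 hybrid design with 100 observed crosses
  (1e−3 relative);
* the additive-vs-additive+dominance comparison: 100 paired 5-fold CV runs
  on fresh 10×10 heterotic systems (family-structured panels, 2 locations,
  all crosses observed, GCA variances 0.5, SCA variance 2.0, residual 1.0);
  the GCA+SCA model must beat both GCA-only variants in ≥90% of runs;
* GWAS null calibration (20 replicates of 500 null markers; KS distance
  below the 1% critical value in ≥19) and power (a marker carrying ~20% of
  the variance at n = 300 must rank first in ≥18 of 20 replicates).

Two details matter for interpreting boundary cases.  First, when a true
component is zero its REML estimate is positive in roughly half of
replicates (the usual boundary-truncation behaviour), so "estimated at the
boundary" is asserted as *flagged at the clamp floor or negligible (≤5% of
the remaining variance)*, not as exactly zero.  Second, the SCA of a cross
with no phenotyped relatives is unpredictable by construction — predictive
gains from the SCA kernel require parental relatedness, which is why the CV
comparison uses family-structured panels (unstructured panels make K₃
off-diagonals vanish and the comparison collapses to noise).

## Known limitations

* Dense linear algebra throughout: O(n³) per AI iteration and O((p+Σqᵢ)³)
  per MME solve; comfortable to a few thousand records/levels, not beyond.
* EM near a zero-variance boundary converges too slowly to be a practical
  sole fitter; it is the robust fallback, not the default.
* Single residual variance (no R-side structures), diploid markers only,
  no pedigree-based relationship matrices, no LD pruning.
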