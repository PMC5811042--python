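# Methods

## The analysis in one paragraph

Relative leukocyte telomere length (RLTL) is measured by qPCR as the
efficiency-corrected ratio of telomeric to single-copy-gene (B2M)
amplification, normalized to a calibrator sample repeated on every plate.
Natural-log RLTL records taken repeatedly on the same cows are modelled with a
random regression animal model: the population mean trajectory over age is a
quadratic Legendre polynomial, and each animal's deviation from it is another
quadratic Legendre polynomial whose coefficients are additive-genetic random
effects with covariance `A ⊗ K` (A = pedigree numerator relationship matrix,
K = coefficient covariance).  REML estimates of K and the residual variance
yield age-specific additive variance `V_A(t) = φ(t) K φ(t)'`, heritability
`h²(t) = V_A / (V_A + V_pe + σ²_e)`, genetic correlations between ages, and
eigenfunctions of the covariance function.  Per-animal BLUP profiles are
clustered into five shape groups, and cluster membership is tested against
productive lifespan (days from birth to culling, right-censored) with a Cox
proportional-hazards model and a Wald test.

## Model

For record *i* of animal *j* at age *t* (months):

```
y_tij = BirthYear_j + GeneticGroup_j + Plate_ij + Row_ij
        + Σ_k φ_k(t) b_k + Σ_k φ_k(t) u_jk [+ pe_j] + e_tij
```

* `φ_k` — Legendre polynomials on the age interval mapped to [−1, 1],
  normalized as `sqrt((2k+1)/2)·P_k` (the quantitative-genetics convention;
  heritabilities and correlations are invariant to the convention as long as
  estimation and evaluation share it).  Default order 2 for both fixed and
  random regressions; the basis age bounds default to the observed data range
  and are recorded in the fit artifacts so trajectories are re-evaluable.
* `u_j ~ N(0, A ⊗ K)` with A from the pedigree (Meuwissen–Luo inbreeding,
  never the F = 0 shortcut); unknown parents are unrelated founders.
* `pe_j ~ N(0, σ²_pe)` — optional scalar permanent-environment effect
  (a full PE covariance matrix is not implemented: the repeated-records
  structure of this design identifies little beyond a scalar, which is also
  the term the analysis ladder examines).
* `e ~ N(0, σ²_e)`, homogeneous by default; age-class-specific residual
  variances are available and compared by AIC/likelihood ratio
  (`test_residual_heterogeneity`), classes with fewer than 10 records being
  merged with a neighbor.

## Estimation

Variance components maximize the restricted likelihood.  One evaluation
assembles Henderson's mixed model equations (the random block carries
`A⁻¹ ⊗ K⁻¹`, sparse) and uses the identities
`log|V| + log|X'V⁻¹X| = log|R| + log|G| + log|C|` and
`y'Py = y'R⁻¹y − ŝ'W'R⁻¹y`, so a single dense Cholesky factorization
suffices.  Scores (exact first derivatives) and the average-information
matrix are computed from the solutions, the inverse coefficient matrix and
sparse-pattern traces.

The optimizer takes Newton steps on the average information **in log-Cholesky
coordinates** of (K, σ²): steps cannot leave the PSD cone and boundary optima
(singular K) are approached smoothly.  Details that matter:

* step halving with an EM fallback (the EM step is monotone) when an AI step
  is rejected;
* an active set freezes coordinates pinned at their lower bounds;
* K eigenvalues are floored at `1e-6 · Var(y)` ("bending"); residual and PE
  variances at `1e-8 · Var(y)`.  A much smaller floor makes `K⁻¹` so large
  that the mixed-model equations lose the digits the optimizer needs;
* convergence: `|Δlog L_R| < 1e-8` and relative parameter change `< 1e-6`;
* on flat ridges along the PSD boundary the AI quadratic model degrades, so
  the fit alternates AI phases with a bounded quasi-Newton (L-BFGS-B) ascent
  on the exact gradient until the projected gradient is numerically zero.
  Non-convergence after six such rounds raises an error carrying the
  likelihood trace.

Starting values: `σ²_e = 0.5·Var(y)`, `K = diag(0.5·Var(y)/(k+1))`.
Asymptotic covariance of the variance parameters = inverse of the final
average-information matrix; solution standard errors come from the diagonal
of the inverse coefficient matrix (prediction-error variances for random
effects).  `AIC = −2 log L_R + 2·(number of variance parameters)`; REML AICs
are only compared across models sharing the same fixed structure (enforced),
with a full-ML likelihood (`ml_loglik`) provided for comparisons that change
the fixed part.  The model ladder (fixed-only → +animal → +pedigree →
+random curves) shares one fixed design, the "+animal without pedigree" step
being the same model with A = I.  A difference of 2 AIC units is the
significance yardstick; within 2 units the simpler model is preferred.

Backward elimination of candidate fixed effects uses conditional Wald F-tests
at α = 0.05, refitting after each removal; candidates aliased with the
mandatory design (birth year, genetic group, plate, row) are flagged and
removed first.  Redundant factor *levels* are dropped (last seen) with a log
message; a redundant numeric covariate is an error listing the aliased
columns.

## Derived quantities

* Fixed curve `Σ b_k φ_k(t)` with SE from the fixed-block covariance.
* Animal profiles `Σ u_jk φ_k(t)` (deviations from the fixed curve); SEs use
  the animal's full prediction-error covariance, `sqrt(φ PEV φ')`.  A
  `per_order` mode that ignores coefficient covariances is provided for
  comparison, but the full-covariance mode is the default because dropping
  the covariances misstates the uncertainty wherever coefficients are
  correlated.
* `V_A(t) = φ K φ'`; `h²(t) = V_A/(V_A + σ²_pe + σ²_e(t))` (PE enters the
  denominator only when the term is in the model); genetic correlation
  `r(t₀,t) = φ(t₀)Kφ(t)' / sqrt(V_A(t₀)V_A(t))`.
* SEs of h² and r via the delta method: central finite-difference gradients
  (step `1e-6` of each parameter's scale) sandwiched with the AI covariance.
  Validated in the tests against parametric draws of the variance parameters.
* Eigenvalues of K as percent of total coefficient variance, eigenfunctions
  `Σ v_ik φ_k(t)`; the leading eigenfunction of an intercept-dominated K is
  flat, separating "level" from "shape" variation between animals.
* Trajectory outputs are evaluated on integer months with a 60-month display
  cut-off; computation always uses the full basis range.

## Clustering and survival

Profiles (all on the same age grid) are grouped with a k-medoids-style
iteration under the **discrete Fréchet distance** computed on value sequences
(ground cost `|a_i − b_j|` over monotone couplings; a shared grid removes the
need for a time/value scaling parameter).  Centers update to the pointwise
median of members, accepted only when the within-cluster distance does not
increase, so the total within-distance is non-increasing; initialization is
distance-weighted seeding, and five seeded restarts keep the solution with
the smallest within-distance (single restarts occasionally merge adjacent
shape groups).  Default k = 5: maintain / mild and steep attrition / mild and
steep elongation.

The Cox model is fitted by Newton–Raphson on the Breslow partial likelihood
(productive lifespan in whole days produces ties); the reference level is the
largest cluster; a Wald chi-square over the k−1 coefficients tests the
association.  Complete separation (monotone likelihood) is detected and
reported with a capped coefficient.  The score test at β = 0 reproduces the
classical log-rank statistic on tie-free two-group data.

## Synthetic herd (ground truth)

The generator emulates the study conditions: ~300 phenotyped females
descending from founder sires/dams over two generations (sire–daughter
matings arise by chance, so inbreeding is exercised), one blood sample at
birth plus `1 + Binomial(6, 0.383)` later samples at uniform ages ≤ 60 months
(mean ≈ 4.3 records/animal); fixed effects for birth year (5 levels), genetic
group (2), plate (~25–30, filled sequentially) and row (8).  Defaults:

| quantity | default | why |
| --- | --- | --- |
| K (normalized-basis scale) | diag ≈ (0.020, 0.0010, 0.0003) with small off-diagonals | gives h² ≈ 0.36–0.46 across ages, r_g(birth, 60 mo) ≈ 0.78, ≈94% of coefficient variance on the intercept |
| σ²_e | 0.018 (log scale) | total log-RLTL variance ≈ 0.03, matching a CV of ~16% on the raw scale |
| fixed curve b | (0.05, −0.02, 0.015) | early-life decline then a mild late rise |
| qPCR | E_TEL = 1.93, E_B2M = 1.98, calibrator at fixed Cqs, noise on sample reactions only | noise-free plates invert Eq. (RLTL) exactly; the log-RLTL measurement error is then Gaussian with variance `sd²(ln²E_TEL + ln²E_B2M)` |
| lifespan | exponential, mean 1477 days; censoring rate 0.2 via an independent exponential with rate `r·c/(1−c)`; whole days ≥ 1 | observed censored fraction is exactly Binomial(n, c); day rounding produces the ties Breslow handles |
| cluster hazards | all zero | profile shape is unrelated to lifespan by default, so the Cox p-value is uniform |

Breeding values are drawn by the pedigree Cholesky recursion (founders from
N(0, K); descendants as mid-parent plus a Mendelian-sampling term with
covariance `(0.5 − 0.25(F_s + F_d))·K`) — exact and O(N) without forming A.
Every generative parameter, per-animal coefficient vector and true cluster
label is stored in `truth.json`, so any downstream estimate can be verified.

What the generator does **not** emulate: selection of parents (no truncation
on breeding values), genotypes, lactation-stage covariates, plate-position
artefacts beyond the row factor, or non-Gaussian measurement error.  Passing
tests therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness to real-data pathologies such as selective
sampling or pulsatile telomere dynamics.

## Problem sizes used in the checks

Oracle-equivalence checks use 30-animal / ~90-record order-1 datasets with a
well-conditioned K (an interior REML optimum; at the PSD boundary the
likelihood ridge makes parameter comparisons between independent optimizers
ill-posed).  Parameter recovery uses 20 replicate herds of 500 phenotyped
cows; the model-selection ladder uses 250-cow herds from 10 sires with
amplified slope/curvature variance (genuine pedigree-structured curve
variation — with the study-default K the curve step adds only ~2–3 AIC units,
exactly the marginal signal the source design reports).  The Wald-test
calibration uses 1000 null replicates at n = 244 with ~20% censoring.

## Known limitations

* REML AICs across different *fixed* structures are not comparable; the
  ladder avoids this by sharing the fixed design, and `ml_loglik` exists for
  the rest.
* The AI asymptotic covariance is unreliable for parameters estimated at or
  near the PSD boundary; delta-method SEs inherit that.
* The discrete Fréchet distance is a max-type metric: single-age outliers
  can dominate; profiles are BLUPs and therefore smooth, which mitigates
  this.
* Heterogeneous residual classes are step functions of age; smoothly varying
  residual variance is out of scope.
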