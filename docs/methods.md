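# Methods

This note documents the statistical models implemented in `sexallometry`,
their assumptions, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical choices that matter. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The allometric mixed model

Static allometry — trait covariation with body size across adults of one
species — is modelled per trait on the log-log scale. For animal *i* with
body weight *w<sub>i</sub>* (grams), trait value *y<sub>i</sub>* (> 0 after
cleaning), sex indicator *m<sub>i</sub>* (1 = male) and centred covariate
*x<sub>i</sub>* = log *w<sub>i</sub>* − mean(log *w*):

```
log y_i = β0 + β1 x_i + β2 m_i + β3 m_i x_i
          + u_batch(i)
          + a_mg(i) + b_mg(i) x_i
          + a_strain(i) + b_strain(i) x_i
          + ε_i
```

- β0, β1: female intercept and allometric slope (exponent); β2, β3: male −
  female contrasts. Because *x* is grand-mean-centred over both sexes, β0 and
  β0+β2 are predicted log values for an average-weight female/male, and β2 is
  a log response ratio (lnRR).
- `batch` (same-day cohort) has a random intercept, variance σ²τ_b.
- `metadata_group` (experimental-condition identifier) and `substrain`
  (genetic background) each get a correlated random intercept + random weight
  slope with an unstructured 2×2 covariance. Random terms whose grouping
  factor has a single level are dropped and recorded (`dropped_random_terms`).
- Residuals are heteroscedastic by sex: ε_i ~ N(0, σ_f²) for females,
  N(0, σ_m²) for males. The ratio σ_m/σ_f is a free parameter.

Assumptions: log-linearity of the trait–weight relationship (power-law
allometry), Gaussian residuals on the log scale, and exchangeable animals
within grouping-factor levels. Traits with zero or negative values must be
shifted to the ratio scale first (§4).

### Estimation

REML via the scaled-covariance (penalized least squares) formulation: all
random-effect covariances are expressed relative to σ_f² through a relative
Cholesky factor Λ(θ); θ collects log scales (intercept-only terms), a
log-Cholesky triple per 2×2 block, and the log residual-SD ratio. For fixed θ
the fixed effects and σ_f² have closed-form profiles, so the optimiser works
in ≤ 8 dimensions regardless of n. Per-sex cross-products are precomputed
once; each criterion evaluation is small dense algebra (q×q, q = total random
effects, plus one O(n) residual pass).

The restricted log-likelihood convention, matched exactly by the dense-matrix
oracle in the tests, is

```
-2 l_R = (n-p) log 2π + log|V| + log|X'V⁻¹X| + r'V⁻¹r
```

Numerical choices:

- Optimiser: L-BFGS-B (finite-difference gradients, step 1e-6, criterion
  tolerance 1e-8) followed by a Nelder–Mead polish; up to 3 jittered restarts
  before a trait is declared non-convergent (`converged=False`; the pipeline
  skips such traits rather than aborting).
- Degenerate parameter points (failed factorizations at extreme scales)
  return a large finite penalty sloping back toward the feasible region —
  returning +inf breaks gradient line searches.
- Variance parameters are bounded at |log scale| ≤ 8 (variances within e^±16
  of σ_f²), which acts as a proper boundary for effectively-zero components.
- Wald inference for β uses t statistics with df = n − rank(X) − (levels of
  the factor with most levels); at phenotyping-scale n this is
  indistinguishable from the normal approximation (the OLS-equivalence test
  checks the df rule exactly in the degenerate case). This df rule is a
  documented substitute — the original software's convention is not restated
  anywhere authoritative.
- SEs for the per-sex residual SDs come from the observed information of the
  unprofiled criterion on the (log σ_f, log ratio) scale (central-difference
  Hessian, step 1e-4), back-transformed; if the Hessian is not positive
  definite the analytic fallback SE(log sd) = 1/√(2(n_sex − 1)) is used.
- `min_per_sex` defaults to 20: below that the trait is skipped (no floor is
  stated anywhere authoritative; 20 keeps the heteroscedastic variance
  estimate stable).

### Derived quantities

- **Marginal/conditional R²** (variance-partition form): R²m =
  var(Xβ̂) / (var(Xβ̂) + Σ intercept-scale random variances + mean of the two
  residual variances); R²c adds the random-effect variance to the numerator.
  Random-slope variance is deliberately excluded from the denominator (the
  intercept-scale convention); with centred *x* its observation-weighted
  contribution at x = 0 is zero.
- **Sub-strain comparison**: the model is refit without the sub-strain term
  (identical fixed effects, so restricted likelihoods are comparable);
  ΔAIC = AIC_without − AIC_with, and the LRT p-value for the 3 sub-strain
  covariance parameters is halved as a 50:50 boundary-mixture correction.
  Applicable only when > 1 sub-strain is present.
- **Variance missed by a common slope**: refit without the sex × weight
  interaction; report (R²m_full − R²m_reduced)/R²m_full ∈ [0, 1]. On exact
  noise-free two-line data the heteroscedastic variance model degenerates (a
  likelihood spike at zero female variance), so the closed-form check of this
  quantity is run homoscedastic.

## 2. Sex-difference inference

- **Scenario classification** at α = 0.05 (configurable; strict inequality,
  ties at α are non-significant): A = slope contrast significant only,
  B = intercept only, C = both, NS = neither. Labels partition all converged
  units. No across-trait multiplicity correction is applied (a
  Benjamini–Hochberg switch exists but is off by default, matching the
  vote-counting design this mirrors).
- **Residual-SD test** (lnVR): lnVR = ln(sd_m/sd_f) + 1/(2(n_m−1)) −
  1/(2(n_f−1)), SE² = 1/(2(n_m−1)) + 1/(2(n_f−1)), two-sided normal p. The
  same estimate and SE are reused downstream as the `sd_diff` effect size, so
  test and meta-analysis cannot drift apart.
- **Merging correlated traits** (e.g. left/right eye): Fisher's statistic
  X = −2Σln p is rescaled by M_eff/k and referred to χ² with *fractional* df
  2·M_eff, where M_eff = Σ_λ [I(λ≥1) + (λ−⌊λ⌋)] over the eigenvalues of the
  k×k equicorrelation matrix (off-diagonal r = 0.8 by default; closed-form
  eigenvalues 1+(k−1)r and 1−r). Note the estimator is discontinuous at
  r = 1: for identical p-values M_eff → 2 (not 1) as r → 1⁻; this is a
  property of the published fractional-part formula, not a bug. Bias
  directions (male/female) are reported only for unmerged units —
  directionality is meaningless across merged traits.
- **Bias tallies** per functional group: scenario A units tally the slope
  bias, B the intercept bias, C both (a unit whose slope and intercept biases
  point to opposite sexes counts as "mixed"), and all units with significant
  lnVR tally the SD bias.

## 3. Effect sizes and meta-analysis

Four per-trait effect sizes, all male − female: the two model contrasts
(intercept = lnRR, slope) with model SEs; lnVR with its analytic SE; and
model fit as Zr = atanh(√R²m) with variance 1/(n−3) (R²m clipped at
0.999999, flagged). Cohen's *d* is computed on log values (the modelling
scale) with the standard sampling variance (n_f+n_m)/(n_f·n_m) +
d²/(2(n_f+n_m)) and benchmarks 0.2/0.5/0.8; no small-sample (Hedges)
correction, negligible at these n.

**Folded-normal transform** (magnitudes): for signed ES with sampling SE,

```
ES_f  = SE·√(2/π)·exp(−ES²/2SE²) + ES·[1 − 2Φ(−ES/SE)]
SE_f² = ES² + SE² − ES_f²
```

the exact mean/variance of |X|, X ~ N(ES, SE²). SE = 0 maps to (|ES|, 0),
flagged. Folded magnitudes are meta-analysed directly; for the correlation
model they are further log-transformed with the first-order delta method
(es′ = ln es, se′ = se/es) — accurate in the small-CV regime the folded
magnitudes occupy, and checked against Monte Carlo in the tests.

**Multilevel meta-analysis** (one kind at a time, folded scale): y_i = μ +
u_fg + u_tg + u_i + e_i with known sampling variances, REML over the τ²
(log-parameterised, L-BFGS-B with restarts), GLS for μ. 95% CI = μ ±
1.96·se_μ; 95% PI = μ ± 1.96·√(Στ² + se_μ²) — the likely magnitude for a
future trait, carrying the heterogeneity. z rather than t critical values
(configurable consumers can widen; at the k used here the difference is
small). Meta-regression fits functional group as a cell-means moderator with
shared τ²; single-effect levels are excluded with a logged reason.

**Effect-size correlations**: each unit's four log-folded effects are one
observation of a latent 4-vector with per-kind functional-group fixed
effects, a trait-group random effect, an unstructured 4×4 unit-level
covariance (the estimand, reported as a correlation matrix), and known
diagonal sampling covariance. Estimation is marginal ML with profiled fixed
effects, blockwise by trait group; intervals by parametric bootstrap
(percentiles over refits of data simulated from the fitted model). Design
choices: the trait-group covariance is constrained diagonal (cross-kind
correlation is identified at the unit level; freeing both levels with ~300
units is poorly identified), and when every trait group is a singleton the
group effect is dropped entirely (it is then confounded with the unit-level
diagonal). This replaces a Bayesian multivariate sampler with default priors;
at these k, ML point estimates and default-prior posterior means agree
closely, and the substitution is declared in the result metadata
(`n_boot`, `converged`).

## 4. Data cleaning and scales

Rules, in order: drop missing body weight; drop non-positive weight; drop
missing trait values; drop trait values exactly 0; deduplicate specimen IDs
keeping the first occurrence. Every removal is counted in a report;
`n_input = n_kept + n_removed` always, and cleaning is idempotent.
Interval-scale traits (legitimately containing values ≤ 0) are shifted by
`quantum − min(value)` so the minimum becomes one measurement quantum
(default +1); the offset is recorded in provenance. The shift rule is a
declared substitute — it preserves order and positivity and is auditable,
but intercepts of shifted traits are not comparable across different offsets.
Sex tokens are canonicalised case-insensitively to {female, male}; any other
token rejects the row with its row number. Functional-group labels and the
correlated-trait grouping are user inputs (two-column CSV), not derived.

## 5. The synthetic generator

`simulate` inverts the fitted model: lognormal body weights per sex (defaults:
female median 22 g, males 1.2× heavier, log-SD 0.15 — typical adult-mouse
spread), uniform assignment to batches/metadata groups/sub-strains, random
effects drawn from the specified covariances, sex-specific residual noise,
and values exported on the natural scale. Centring is at the sample grand
mean of log weight, so the noise-free limit is an exact power law of weight
relative to the geometric-mean weight. Scenario specs are built by
`spec_from_scenario` (deltas are male − female, nonnegative by convention).

Reproducibility: a single PCG64 generator per trait, seeded by
`SeedSequence(master_seed, spawn_key=crc32(trait_name))` — adding a trait to
a study never perturbs another trait's data, and datasets are byte-stable for
a given seed and numpy version. Traits mapped to the same correlated-trait
group share their latent animals (weights and IDs), so merged-p machinery
sees genuinely correlated traits.

What the generator does **not** emulate: phenotyping-centre effects, litter
structure, age trends, unbalanced group sizes (assignment is uniform;
configurable only through the level counts), non-Gaussian trait noise, and
measurement truncation/rounding. A green end-to-end test therefore
establishes that the estimators recover the stated generating process — not
that real phenotyping data satisfy that process.

### The stated validation world

The recovery and calibration studies in the acceptance tests fix, a priori:
n = 3000/sex (recovery) and 500/sex (type-I calibration, 1000 replicates);
sex contrasts of 0.1 log units where a scenario requires them (a medium,
realistic contrast above the 0.05 floor of interest); σ_f = 0.12 with SD
ratios up to 1.5; 20–30 batches with intercept variance 0.004. Under that
world the Wald intervals are checked for 93–97% coverage, the scenario
confusion-matrix diagonal for ≥ 90%, each test's type-I error for 0.05
within 3 binomial SDs, and the meta-analytic PI for ~95% coverage over 500
simulated hierarchies.

## 6. Known limitations

- The LMM assumes the random-effect structure is correct; no sandwich/robust
  SEs are offered.
- lnVR inference treats the REML residual-SD estimates as if based on n − 1
  df per sex; with many batch levels this is very slightly anticonservative
  (checked empirically to stay within the calibration band).
- The Li–Ji adjustment assumes equicorrelation within a trait group with a
  fixed, user-supplied r; it is not estimated from data.
- Meta-analytic intervals use normal critical values; for very small k a t
  correction would be wider.
- The correlation model's bootstrap refits are expensive (seconds per refit);
  the default 100–200 replicates bound the interval resolution.
- No categorical traits, no centre random effects, no Bayesian fitting.
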