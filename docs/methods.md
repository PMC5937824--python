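# Methods

## Model

For distinguishable dyads with one predictor and one outcome per member,
the actor–partner interdependence model (APIM) is

    Y_m = a_m X_m + p_mf X_f + E_m
    Y_f = a_f X_f + p_fm X_m + E_f

with exogenous covariance φ = cov(X_m, X_f) and residual covariance
ψ = cov(E_m, E_f), residuals independent of the predictors. Assumptions:
joint normality (for likelihood and Wald inference), linearity, one row
per couple sampled independently across couples, and distinguishable roles
(role-specific parameters; exchangeable-dyad designs are rejected at the
data layer). Means carry no structure — the equations have no intercepts
and every reported quantity is a function of the covariance matrix — so
the analysis is covariance-only and the mean vector is treated as
saturated.

Writing B = [[a_m, p_mf], [p_fm, a_f]], the model-implied covariance over
(X_m, X_f, Y_m, Y_f) is

    Σ(θ) = [[φ, φBᵀ], [Bφ, BφBᵀ + ψ]],   θ = (B, φ, ψ), 10 parameters.

## Estimation

The ML discrepancy is F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − 4, with S the
sample covariance (n−1 denominator). Ten parameters match the ten distinct
sample moments, so the unconstrained model is saturated and solved in
closed form: B̂ = S_YX S_XX⁻¹ (each outcome regressed on both predictors),
φ̂ = S_XX, ψ̂ = S_YY − B̂ S_XX B̂ᵀ, F_ML = 0, χ² = 0, df = 0. No optimizer
is involved, which makes the estimates exact and the per-equation OLS
equivalence testable to 1e−8. Closed form requires |corr(X_m, X_f)| <
1 − 1e−10; beyond that a collinearity error is raised rather than a silent
pseudo-inverse.

χ² = c·F_ML with multiplier c = n−1 by default (Wishart convention);
c = n is available via `APIMSpec(chi_square_multiplier="n")`. The choice
only matters in the third decimal of fit statistics at this n, but it is
exposed because software packages differ.

### Standard errors

Unstandardized SEs come from the inverse expected (Fisher) information of
the covariance-structure problem, I_ij = (c/2)·tr(Σ⁻¹ ∂Σ/∂θ_i Σ⁻¹ ∂Σ/∂θ_j),
with analytic ∂Σ/∂θ (Σ is quadratic in θ) and the same multiplier c as χ².
Standardized coefficients β = slope × sd(predictor)/sd(outcome) use
model-implied SDs (equal to sample SDs in the saturated model); their SEs
are delta-method transforms of the full parameter covariance. The two SE
conventions differ noticeably (on the bundled study moments: 0.17 on the
raw slope vs 0.049 on β for the male actor path) and are reported side by
side, never conflated. Monte-Carlo calibration (500 replicates, n = 2000,
and CI coverage at n = 1000) is part of the test suite. Wald z is
reported signed; some published tables print |t| next to negative β.

### Equality constraints

Constraint kinds: `actor_equal` (a_m = a_f), `partner_equal`
(p_mf = p_fm), `actor_eq_partner` within one role's outcome equation. Each
adds df = 1. On the default unstandardized scale, the constrained problem
is solved by quasi-Newton (BFGS) on a concentrated objective: for fixed B
the optimal φ is S_XX and the optimal ψ is the empirical residual
covariance ψ(B) = [−B I] S [−B I]ᵀ, leaving F(B) = ln|ψ(B)| − ln|S_Y·X|
over three free slopes — an exact reparameterization, not a penalty.
Constraints may instead be imposed on the *standardized* scale
(`scale="standardized"`), which matters because the two roles' SDs differ;
there the constraint couples slopes to residual variances, so the full
9-parameter vector is optimised with a log-Cholesky parameterization of
φ and ψ, the constrained slope recovered from its defining quadratic (the
root with the sign of β; for the within-role constraint the relation is
linear, p = a·sd(X_own)/sd(X_partner)). Convergence: BFGS gradient norm
1e−8, max 500 iterations, up to 3 jittered restarts; the `converged` flag
and final gradient norm are reported honestly.

χ²_diff = χ²_c − χ²_u and df_diff = df_c − df_u, p from χ²(df_diff).
Differences in (−1e−6, 0) are numerical noise and clamped to zero; more
negative differences raise a non-nested error. Null calibration (1000
replicates, n = 200, equal true actor effects) verifying mean ≈ 1 and
5% rejection at 3.84 runs in the test suite.

## Data layer

Wide one-row-per-dyad CSV is canonical (`<variable>_<role>` columns,
unique `dyad_id`); a long-to-wide pivot helper exists but long data are
not a fitting input. Missing data are handled by listwise deletion per
analysis with the post-deletion n reported. Summary statistics
(variables/means/sds/correlations/n as JSON) are first-class inputs since
they are sufficient for everything here; SDs use the n−1 denominator
throughout, matching standard "mean ± SD" reporting. Correlation matrices
printed to 2 dp can be slightly indefinite: eigenvalues above −1e−8 pass
validation, anything worse raises unless the explicit eigenvalue-clipping
repair (clip at 0, rescale to unit diagonal) is requested — data are never
silently altered. The bundled 12×12 study matrix needs the repair (min
eigenvalue ≈ −0.0016); every 4×4 analysis block is PD without it.

## Questionnaire scoring

PHQ-9: 9 items scored 0–3, total = item sum (0–27), optionally prorated
(sum × 9/answered) up to a configurable missing-item allowance (default
0, since the bundled study analysed complete responses). FertiQoL core:
24 items scored 0–4 in four 6-item subscales (Emotional, Mind/Body,
Relational, Social); each subscale = mean(answered) × 25, total =
mean over *all* answered items × 25 (0–100; the ×25 is the only linear
map from 0–4 onto 0–100). A subscale needs ≥ 3 of 6 items answered
(configurable). The scorer consumes pre-oriented items (higher = better
QoL); official FertiQoL forms contain reverse-keyed items whose keying
varies by distribution, so an optional user-supplied `reverse_key` mask
(v → 4 − v) is accepted rather than hard-coding a keying.

## Synthetic data

`simulate_dyads` is the literal forward model: (X_m, X_f) multivariate
normal (μ_x, φ), residuals multivariate normal (0, ψ) independent of X,
outcomes from the two equations; a single integer seed (PCG64) determines
the whole table. Defaults mirror the bundled study's fitted structure —
n = 180 couples, depression-scale predictors (SDs 5.47/5.78, r = 0.18),
slopes (−1.72, −1.64, −0.30, −0.36) and residual covariance
[[156.9, 41.3], [41.3, 159.1]] (residual r ≈ 0.26) — so simulation
exercises the model at realistic signal-to-noise. `match_moments`
materialises an n-row table whose *sample* moments equal a target summary
exactly (centre a normal draw, whiten against its empirical covariance,
re-colour with the target Cholesky factor, shift means; needs n ≥ p + 1),
making published tables interchangeable with raw data in every code path.
`recovery_experiment` tabulates bias, empirical SD, mean reported SE and
Wald-CI coverage per path over a seeded grid of sample sizes.

What the generator does *not* emulate: non-normal or skewed item
distributions (real PHQ-9 totals are right-skewed and floor-bounded),
missingness mechanisms, dyad-level covariates, or measurement error in
the scale scores. Passing recovery/calibration tests therefore certify
the estimator under the model's own assumptions, not robustness to their
violation.

## Numerical and design choices

- Problem sizes in the shipped tests: oracle equivalence over 100
  simulated datasets; null calibration with 1000 replicates at n = 200;
  recovery at n = 10⁵ plus coverage with 500 replicates at n = 1000 —
  large enough for stable Monte-Carlo bands (e.g. ±0.02 on a 5% rejection
  rate), small enough that the whole suite runs in well under a minute of
  compute per heavy test.
- Reported p-values are two-sided everywhere. Correlation p-values use the
  exact t transform t = r√((n−2)/(1−r²)); |r| = 1 maps to p = 0.
- McNemar's test defaults to no continuity correction ((b−c)²/(b+c);
  b = c gives exactly χ² = 0, p = 1; b + c = 0 gives χ² = 0 by
  convention); the corrected variant is available.
- Significance stars default to 0.05/0.01/0.001 (configurable).
- Paired t is signed with (mean_b − mean_a); published tables sometimes
  print |t|.
- Report rendering: 3 decimals for r/β, 2 for t/χ², p shown as "<0.001"
  below threshold in TSV/markdown while JSON always keeps raw values; the
  report bundle (tables + manifest with config hash, seed, version) is a
  deterministic function of (inputs, config, seed).

## Known limitations

- Only the covariance-structure (SEM) estimation route is implemented;
  multilevel and pooled-regression formulations of the APIM are out of
  scope, as are latent measurement models and the partner/actor ratio
  parameterization.
- Indistinguishable dyads and groups of k > 2 members are rejected.
- Exact reproduction of third-party software's constrained-fit χ² values
  from 2-dp published inputs is not attainable (input rounding plus
  unstated multiplier/scale conventions); equality tests are validated by
  direction, significance pattern and Monte-Carlo calibration instead.
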