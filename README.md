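# dyadkit

Actor–partner interdependence modelling for distinguishable dyads — built
for researchers analysing couple-level data (e.g. depression and quality of
life in couples experiencing infertility), where the two members of each
couple are *not* independent observations.

## The problem and the model

When both members of a couple are measured, their scores correlate within
the couple, so person-level regression is invalid. The actor–partner
interdependence model (APIM) takes the **dyad** as the sampling unit and
estimates, simultaneously:

```
Y_m = a_m X_m + p_mf X_f + E_m
Y_f = a_f X_f + p_fm X_m + E_f
```

* `a_m`, `a_f` — **actor effects**: one's own predictor (e.g. PHQ-9
  depression) on one's own outcome (e.g. FertiQoL quality of life);
* `p_mf`, `p_fm` — **partner effects**: the partner's predictor on one's
  own outcome (`p_mf` carries the f-member's predictor into the m-member's
  outcome);
* cov(X_m, X_f) = φ — partners' predictors may correlate (compositional
  effect); cov(E_m, E_f) = ψ — residual non-independence.

Estimation is maximum-likelihood covariance-structure analysis: minimise
`F_ML = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p` over the model-implied
covariance Σ(θ) of (X_m, X_f, Y_m, Y_f). The unconstrained APIM is
saturated (χ² = 0, df = 0) and solved in closed form; equality questions
("is the male actor effect equal to the female one?") are answered by
refitting with the constraint imposed and referring
`χ²_diff = χ²_constrained − χ²_unconstrained` to χ²(1).

Because every quantity is a function of the covariance matrix, the model
fits equally well from **raw dyad tables** (wide CSV, one row per couple),
from **published summary statistics** (means, SDs, correlations, n), or
from **simulated data** — and a published table can be turned into an
exactly moment-matched raw dataset with `match_moments`.

Also included: PHQ-9 and FertiQoL-core questionnaire scoring, paired
*t* tests (raw or from moments), McNemar's test, correlation matrices with
significance stars, Cronbach's α, a seeded APIM forward simulator with a
parameter-recovery harness, and a CLI (`dyadkit fit`, `fit-summary`,
`test-equality`, `simulate`, `score`, `report`).

## Worked example

The package bundles the summary statistics of a published cross-sectional
study of 180 infertile couples (PHQ-9 depression, FertiQoL core QoL for
both partners):

```python
from dyadkit import datasets, fit_apim, run_all_equality_tests
from dyadkit.constraints import equality_tests_table

fit = fit_apim(datasets.couples_summary("qol"))
print(fit.summary())
```

```
APIM (depression -> qol; roles male/female; n = 180 dyads)
chi2 = 0.0000, df = 0, p = 1.0000 [n_minus_1 multiplier]; converged = True

path               est      beta       se  se_beta        z         p
actor_m        -1.7233   -0.5914   0.1740   0.0488   -9.904  4.01e-23
actor_f        -1.6379   -0.5876   0.1658   0.0488   -9.878 5.189e-23
partner_mf     -0.2856   -0.1036   0.1647   0.0596   -1.734   0.08287
partner_fm     -0.3659   -0.1242   0.1752   0.0593   -2.088   0.03678
predictor correlation r = 0.180; residual correlation r = 0.261
```

Reading: one PHQ-9 point of a man's own depression costs him 1.72 points
of FertiQoL (β ≈ −0.59); his wife's depression costs him a further 0.29
points per PHQ-9 point (β ≈ −0.10, marginal). `beta` are standardized
coefficients (slope × SD ratio on the model-implied scale); `se` is the
expected-information SE of the raw slope, `se_beta` the delta-method SE of
the standardized one.

```python
tests = run_all_equality_tests(datasets.couples_summary("qol"))
print(equality_tests_table(tests).to_string(index=False))
```

```
             constraint  chi_sq_diff  df            p  significant  converged
            actor_equal     0.120559   1 7.284293e-01        False       True
          partner_equal     0.106454   1 7.442177e-01        False       True
  actor_vs_partner_male    28.186948   1 1.101448e-07         True       True
actor_vs_partner_female    22.141410   1 2.532867e-06         True       True
```

Actor (and partner) effects do not differ between the sexes, but within
each sex the actor effect is clearly larger than the partner effect.

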