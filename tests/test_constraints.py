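import numpy as np
import pytest

from dyadkit import datasets
from dyadkit.apim import APIM, APIMParameters, APIMSpec, fit_apim, model_implied_sigma
from dyadkit.constraints import (
    ConstraintError,
    ConstraintSpec,
    chisq_difference,
    equality_tests_table,
    fit_constrained,
    run_all_equality_tests,
)
from dyadkit.dyad_data import InsufficientRowsError, MomentSummary
from dyadkit.simulate import SimulationConfig, match_moments, simulate_dyads

from conftest import random_apim_summary

VARS = ["depression_male", "depression_female", "qol_male", "qol_female"]


def _symmetric_summary(n=200) -> MomentSummary:
    """Moments exactly invariant under swapping roles: all equality
    constraints hold in the population and in the sample."""
    R = np.array([
        [1.00, 0.18, -0.60, -0.20],
        [0.18, 1.00, -0.20, -0.60],
        [-0.60, -0.20, 1.00, 0.36],
        [-0.20, -0.60, 0.36, 1.00],
    ])
    return MomentSummary(VARS, [5, 5, 70, 70], [5.5, 5.5, 16.0, 16.0], R, n=n)


def _summary_from_params(params: APIMParameters, n=400) -> MomentSummary:
    sigma = model_implied_sigma(params)
    d = np.sqrt(np.diag(sigma))
    R = sigma / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return MomentSummary(VARS, np.zeros(4), d, R, n=n)


class TestFitConstrained:
    @pytest.mark.parametrize("kind,role", [
        ("actor_equal", None),
        ("partner_equal", None),
        ("actor_eq_partner", "male"),
        ("actor_eq_partner", "female"),
    ])
    @pytest.mark.parametrize("scale", ["unstandardized", "standardized"])
    def test_df_one_and_fml_nonnegative(self, qol_summary, kind, role, scale):
        fit = fit_constrained(qol_summary, ConstraintSpec(kind, role=role, scale=scale))
        assert fit.df == 1
        assert fit.fml >= 0
        assert fit.converged

    def test_constraint_actually_binds(self, qol_summary):
        fit = fit_constrained(qol_summary, ConstraintSpec("actor_equal"))
        assert fit.paths["actor_m"] == pytest.approx(fit.paths["actor_f"], abs=1e-8)
        fit = fit_constrained(qol_summary, ConstraintSpec("partner_equal"))
        assert fit.paths["partner_mf"] == pytest.approx(fit.paths["partner_fm"], abs=1e-8)
        fit = fit_constrained(qol_summary, ConstraintSpec("actor_eq_partner", role="male"))
        assert fit.paths["actor_m"] == pytest.approx(fit.paths["partner_mf"], abs=1e-8)

    def test_standardized_constraint_binds_on_beta_scale(self, qol_summary):
        fit = fit_constrained(
            qol_summary, ConstraintSpec("actor_equal", scale="standardized"))
        assert fit.standardized["actor_m"] == pytest.approx(
            fit.standardized["actor_f"], abs=1e-6)
        # predictor SDs differ across roles, so the raw slopes must differ
        assert fit.paths["actor_m"] != pytest.approx(fit.paths["actor_f"], abs=1e-4)

    def test_non_binding_constraint_gives_zero_chi_square(self):
        fit = fit_constrained(_symmetric_summary(), ConstraintSpec("actor_equal"))
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)

    def test_consistency_under_true_equality(self):
        # data generated with exactly equal actor slopes
        cfg = SimulationConfig(
            n_dyads=10**5, slopes=(-1.7, -1.7, -0.30, -0.36), seed=5,
        )
        table = simulate_dyads(cfg)
        model = APIM.from_dyad_table(table, cfg.apim_spec())
        fit = fit_constrained(model, ConstraintSpec("actor_equal"))
        assert fit.paths["actor_m"] == pytest.approx(-1.7, abs=0.02)
        # null chi-square: below the 99% point of chi2(1)
        assert fit.chi_square < 6.63

    def test_standardized_equal_but_unstandardized_not(self):
        # betas equal by construction, raw slopes differ via unequal SDs
        params = APIMParameters(
            a_m=-1.0, a_f=-2.0, p_mf=-0.2, p_fm=-0.4,
            phi=np.array([[4.0, 1.0], [1.0, 1.0]]),
            psi=np.array([[6.0, 1.0], [1.0, 6.0]]),
        )
        sigma = model_implied_sigma(params)
        sd = np.sqrt(np.diag(sigma))
        beta_m = params.a_m * sd[0] / sd[2]
        beta_f = params.a_f * sd[1] / sd[3]
        # tune a_f so the standardized actors coincide exactly
        a_f = beta_m * sd[3] / sd[1]
        # recompute sigma with the adjusted slope until fixed point (sd[3] shifts)
        for _ in range(200):
            params = APIMParameters(
                a_m=-1.0, a_f=a_f, p_mf=-0.2, p_fm=-0.4,
                phi=params.phi, psi=params.psi,
            )
            sigma = model_implied_sigma(params)
            sd = np.sqrt(np.diag(sigma))
            new_a_f = (params.a_m * sd[0] / sd[2]) * sd[3] / sd[1]
            if abs(new_a_f - a_f) < 1e-14:
                break
            a_f = new_a_f
        summary = _summary_from_params(params, n=300)
        std_fit = fit_constrained(
            summary, ConstraintSpec("actor_equal", scale="standardized"))
        raw_fit = fit_constrained(summary, ConstraintSpec("actor_equal"))
        assert std_fit.chi_square == pytest.approx(0.0, abs=1e-5)
        assert raw_fit.chi_square > 1.0

    def test_invalid_kind_and_missing_role(self):
        with pytest.raises(ConstraintError):
            ConstraintSpec("slope_equal")
        with pytest.raises(ConstraintError):
            ConstraintSpec("actor_eq_partner")


class TestChisqDifference:
    def test_nonnegative_and_clamped(self, rng):
        for _ in range(10):
            summary = random_apim_summary(rng, n=80)
            unconstrained = fit_apim(summary)
            constrained = fit_constrained(summary, ConstraintSpec("actor_equal"))
            res = chisq_difference(constrained, unconstrained)
            assert res.chi_sq_diff >= 0.0
            assert res.df_diff == 1
            assert 0.0 <= res.p <= 1.0

    def test_identical_fits_rejected_as_non_nested(self, qol_summary):
        fit = fit_apim(qol_summary)
        with pytest.raises(ConstraintError):
            chisq_difference(fit, fit)

    def test_mismatched_data_rejected(self, qol_summary, rng):
        other = random_apim_summary(rng)
        con = fit_constrained(qol_summary, ConstraintSpec("actor_equal"))
        unc = fit_apim(other)
        with pytest.raises(ConstraintError):
            chisq_difference(con, unc)

    def test_mismatched_multiplier_rejected(self, qol_summary):
        con = fit_constrained(qol_summary, ConstraintSpec("actor_equal"))
        unc = fit_apim(qol_summary, APIMSpec("depression", "qol",
                                             chi_square_multiplier="n"))
        with pytest.raises(ConstraintError):
            chisq_difference(con, unc)

    def test_chi_square_diff_shrinks_to_zero_along_parameter_path(self):
        # as the generating actor difference delta -> 0, the actor-equality
        # chi-square difference decreases continuously to ~0
        diffs = []
        for delta in (1.0, 0.5, 0.2, 0.0):
            params = APIMParameters(
                a_m=-1.7, a_f=-1.7 + delta, p_mf=-0.3, p_fm=-0.36,
                phi=np.array([[29.9, 5.7], [5.7, 33.4]]),
                psi=np.array([[156.9, 41.3], [41.3, 159.1]]),
            )
            summary = _summary_from_params(params, n=400)
            res = chisq_difference(
                fit_constrained(summary, ConstraintSpec("actor_equal")),
                fit_apim(summary),
            )
            diffs.append(res.chi_sq_diff)
        assert all(a > b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] == pytest.approx(0.0, abs=1e-6)


class TestScaleInvariances:
    def test_standardized_tests_invariant_to_any_positive_rescaling(self, rng):
        summary = random_apim_summary(rng, n=120)
        c = np.array([2.0, 0.5, 7.0, 0.1])
        scaled = MomentSummary(summary.variables, summary.means * c,
                               summary.sds * c, summary.correlations, summary.n)
        for kind, role in [("actor_equal", None), ("actor_eq_partner", "male")]:
            cs = ConstraintSpec(kind, role=role, scale="standardized")
            d1 = chisq_difference(fit_constrained(summary, cs), fit_apim(summary))
            d2 = chisq_difference(fit_constrained(scaled, cs), fit_apim(scaled))
            assert d2.chi_sq_diff == pytest.approx(d1.chi_sq_diff, abs=2e-4)

    def test_unstandardized_tests_invariant_to_blockwise_common_rescaling(self, rng):
        summary = random_apim_summary(rng, n=120)
        cx, cy = 3.0, 0.25  # common predictor factor, common outcome factor
        c = np.array([cx, cx, cy, cy])
        scaled = MomentSummary(summary.variables, summary.means * c,
                               summary.sds * c, summary.correlations, summary.n)
        cs = ConstraintSpec("actor_equal")
        d1 = chisq_difference(fit_constrained(summary, cs), fit_apim(summary))
        d2 = chisq_difference(fit_constrained(scaled, cs), fit_apim(scaled))
        assert d2.chi_sq_diff == pytest.approx(d1.chi_sq_diff, rel=1e-5, abs=1e-8)


class TestRunAllEqualityTests:
    def test_study_moments_reproduce_published_pattern(self, qol_summary):
        tests = run_all_equality_tests(qol_summary)
        assert [t.label for t in tests] == [
            "actor_equal", "partner_equal",
            "actor_vs_partner_male", "actor_vs_partner_female",
        ]
        by = {t.label: t for t in tests}
        assert by["actor_equal"].chi_sq_diff < 3.84
        assert by["partner_equal"].chi_sq_diff < 3.84
        assert by["actor_vs_partner_male"].p < 0.001
        assert by["actor_vs_partner_female"].p < 0.001

    def test_all_non_significant_when_every_slope_equal(self):
        fitted = run_all_equality_tests(_symmetric_summary())
        # actor/partner equalities hold exactly; within-role equality does not
        by = {t.label: t for t in fitted}
        assert by["actor_equal"].chi_sq_diff == pytest.approx(0.0, abs=1e-6)
        assert by["partner_equal"].chi_sq_diff == pytest.approx(0.0, abs=1e-6)

    def test_table_rendering_and_decision_column(self, qol_summary):
        tab = equality_tests_table(run_all_equality_tests(qol_summary), alpha=0.05)
        assert list(tab["constraint"]) == [
            "actor_equal", "partner_equal",
            "actor_vs_partner_male", "actor_vs_partner_female",
        ]
        assert tab["significant"].tolist() == [False, False, True, True]
        assert tab["converged"].all()

    def test_too_few_dyads_rejected(self):
        cfg = SimulationConfig(n_dyads=4, seed=3)
        with pytest.raises(InsufficientRowsError):
            run_all_equality_tests(simulate_dyads(cfg), cfg.apim_spec())
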