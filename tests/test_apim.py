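import math

import numpy as np
import pytest

from dyadkit import datasets
from dyadkit.apim import (
    APIM,
    APIMParameters,
    APIMSpec,
    CollinearPredictorsError,
    PATHS,
    f_ml,
    fit_apim,
    model_implied_sigma,
    standardized_solution,
    wald_tests,
)
from dyadkit.dyad_data import (
    InsufficientRowsError,
    MomentSummary,
    NotPositiveSemidefiniteError,
)
from dyadkit.simulate import SimulationConfig, match_moments, simulate_dyads

from conftest import random_apim_summary


def _ols_slopes(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Independent per-equation least-squares oracle (brute force)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B = np.empty((2, 2))
    for eq in range(2):
        coef, *_ = np.linalg.lstsq(Xc, Yc[:, eq], rcond=None)
        B[eq] = coef
    return B


def _std_oracle(summary: MomentSummary) -> dict[str, float]:
    """Partial-regression formula on the correlation scale (hand algebra).

    beta_actor_m = (r_YmXm - r_YmXf r_XmXf) / (1 - r_XmXf^2), etc.
    """
    R = summary.correlations
    rxx = R[0, 1]
    den = 1.0 - rxx**2
    return {
        "actor_m": (R[2, 0] - R[2, 1] * rxx) / den,
        "partner_mf": (R[2, 1] - R[2, 0] * rxx) / den,
        "partner_fm": (R[3, 0] - R[3, 1] * rxx) / den,
        "actor_f": (R[3, 1] - R[3, 0] * rxx) / den,
    }


class TestModelImpliedSigma:
    def test_zero_slopes_block_diagonal(self):
        phi = np.array([[2.0, 0.5], [0.5, 1.0]])
        psi = np.array([[3.0, 1.0], [1.0, 2.0]])
        params = APIMParameters(a_m=0, a_f=0, p_mf=0, p_fm=0, phi=phi, psi=psi)
        sigma = model_implied_sigma(params)
        assert sigma[:2, :2] == pytest.approx(phi)
        assert sigma[2:, 2:] == pytest.approx(psi)
        assert sigma[2:, :2] == pytest.approx(np.zeros((2, 2)))

    def test_single_actor_path(self):
        params = APIMParameters(a_m=1.0, a_f=0, p_mf=0, p_fm=0,
                                phi=np.eye(2), psi=np.eye(2))
        sigma = model_implied_sigma(params)
        assert sigma[2, 2] == pytest.approx(2.0)   # var(Y_m) = 1 + 1
        assert sigma[2, 0] == pytest.approx(1.0)   # cov(X_m, Y_m)
        assert sigma == pytest.approx(sigma.T)


class TestFml:
    def test_zero_at_equality(self, rng):
        A = rng.standard_normal((4, 6))
        S = A @ A.T / 6
        assert f_ml(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # S = I2, sigma = 2 I2: F = ln 4 + 1 - 0 - 2
        assert f_ml(np.eye(2), 2 * np.eye(2)) == pytest.approx(math.log(4) - 1)

    def test_strictly_positive_off_optimum(self, rng):
        for _ in range(25):
            A = rng.standard_normal((3, 5))
            S = A @ A.T / 5
            B = rng.standard_normal((3, 5))
            sigma = B @ B.T / 5 + 1e-6 * np.eye(3)
            if np.allclose(S, sigma):
                continue
            assert f_ml(S, sigma) > 0


class TestSaturatedFit:
    def test_reproduces_sample_covariance(self, rng):
        summary = random_apim_summary(rng)
        fit = fit_apim(summary)
        assert fit.implied_sigma == pytest.approx(summary.covariance(), abs=1e-8)
        assert fit.chi_square < 1e-6
        assert fit.df == 0
        assert fit.converged

    def test_slopes_equal_ols_oracle(self, rng):
        cfg = SimulationConfig(n_dyads=300, seed=77)
        table = simulate_dyads(cfg)
        fit = fit_apim(table, cfg.apim_spec())
        data = table.data
        X = data[["x_male", "x_female"]].to_numpy()
        Y = data[["y_male", "y_female"]].to_numpy()
        B = _ols_slopes(X, Y)
        assert fit.params.slope_matrix == pytest.approx(B, abs=1e-8)

    def test_zero_cross_covariance_gives_zero_slopes(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.3
        R[2, 3] = R[3, 2] = 0.5
        summary = MomentSummary(
            ["depression_male", "depression_female", "qol_male", "qol_female"],
            [0, 0, 0, 0], [1.0, 1.0, 2.0, 2.0], R, n=50,
        )
        fit = fit_apim(summary)
        for p in PATHS:
            assert fit.paths[p] == pytest.approx(0.0, abs=1e-12)
            assert fit.zvalues[p] == pytest.approx(0.0, abs=1e-12)
            assert fit.pvalues[p] == pytest.approx(1.0)
        assert fit.params.psi == pytest.approx(fit.model.S[2:, 2:], abs=1e-12)


class TestStandardizedSolution:
    def test_matches_partial_regression_oracle_exactly(self, qol_summary):
        fit = fit_apim(qol_summary)
        oracle = _std_oracle(qol_summary)
        for p in PATHS:
            assert fit.standardized[p] == pytest.approx(oracle[p], abs=1e-10)

    def test_equal_sds_make_beta_equal_slope(self):
        R = np.eye(4)
        R[0, 2] = R[2, 0] = -0.4
        summary = MomentSummary(
            ["depression_male", "depression_female", "qol_male", "qol_female"],
            [0, 0, 0, 0], [2.0, 2.0, 2.0, 2.0], R, n=40,
        )
        fit = fit_apim(summary)
        for p in PATHS:
            assert fit.standardized[p] == pytest.approx(fit.paths[p], abs=1e-12)

    def test_beta_is_slope_rescaled_by_model_sds(self, qol_summary):
        fit = fit_apim(qol_summary)
        sigma = fit.implied_sigma
        sd = np.sqrt(np.diag(sigma))
        assert fit.standardized["actor_m"] == pytest.approx(
            fit.paths["actor_m"] * sd[0] / sd[2], abs=1e-12
        )

    def test_functional_surface(self, qol_summary):
        fit = fit_apim(qol_summary)
        assert standardized_solution(fit) == fit.standardized
        wt = wald_tests(fit)
        assert wt["actor_m"] == (fit.bse["actor_m"], fit.zvalues["actor_m"],
                                 fit.pvalues["actor_m"])


class TestInvariances:
    def test_scale_equivariance(self, rng):
        summary = random_apim_summary(rng)
        fit = fit_apim(summary)
        c = 3.7
        scaled = MomentSummary(
            summary.variables, summary.means * np.array([c, 1, 1, 1]),
            summary.sds * np.array([c, 1, 1, 1]), summary.correlations, summary.n,
        )
        fit2 = fit_apim(scaled)
        # male predictor scaled by c: its two outgoing slopes divide by c
        assert fit2.paths["actor_m"] == pytest.approx(fit.paths["actor_m"] / c)
        assert fit2.paths["partner_fm"] == pytest.approx(fit.paths["partner_fm"] / c)
        assert fit2.paths["actor_f"] == pytest.approx(fit.paths["actor_f"])
        for p in PATHS:
            assert fit2.standardized[p] == pytest.approx(fit.standardized[p], abs=1e-10)
            assert fit2.zvalues[p] == pytest.approx(fit.zvalues[p], abs=1e-8)
        assert fit2.chi_square == pytest.approx(fit.chi_square, abs=1e-10)

    def test_role_symmetry(self, rng):
        summary = random_apim_summary(rng)
        fit = fit_apim(summary, APIMSpec("depression", "qol", ("male", "female")))
        # same data, roles listed in the opposite order
        fit2 = fit_apim(summary, APIMSpec("depression", "qol", ("female", "male")))
        assert fit2.paths["actor_m"] == pytest.approx(fit.paths["actor_f"])
        assert fit2.paths["actor_f"] == pytest.approx(fit.paths["actor_m"])
        assert fit2.paths["partner_mf"] == pytest.approx(fit.paths["partner_fm"])
        assert fit2.paths["partner_fm"] == pytest.approx(fit.paths["partner_mf"])
        assert fit2.params.phi == pytest.approx(fit.params.phi[::-1, ::-1])
        assert fit2.params.psi == pytest.approx(fit.params.psi[::-1, ::-1])


class TestWaldCalibration:
    def test_reported_se_matches_monte_carlo_sd(self):
        # empirical SD of the estimates over 500 replicates at n = 2000
        # should match the mean reported SE within 10%
        base = SimulationConfig(seed=2024)
        reps, n = 500, 2000
        ss = np.random.SeedSequence(base.seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(reps)]
        ests = {p: np.empty(reps) for p in PATHS}
        ses = {p: np.empty(reps) for p in PATHS}
        for r in range(reps):
            cfg = SimulationConfig(n_dyads=n, seed=seeds[r])
            fit = fit_apim(simulate_dyads(cfg), cfg.apim_spec())
            for p in PATHS:
                ests[p][r] = fit.paths[p]
                ses[p][r] = fit.bse[p]
        for p in PATHS:
            assert ses[p].mean() == pytest.approx(ests[p].std(ddof=1), rel=0.10)

    def test_actor_effects_strongly_significant_on_study_moments(self, qol_summary):
        fit = fit_apim(qol_summary)
        assert abs(fit.zvalues["actor_m"]) > 9
        assert abs(fit.zvalues["actor_f"]) > 9
        assert fit.pvalues["actor_m"] < 0.001


class TestErrors:
    def test_collinear_predictors(self):
        S = np.array([
            [1.0, 1.0, 0.2, 0.1],
            [1.0, 1.0, 0.2, 0.1],
            [0.2, 0.2, 1.0, 0.3],
            [0.1, 0.1, 0.3, 1.0],
        ])
        with pytest.raises((CollinearPredictorsError, NotPositiveSemidefiniteError)):
            APIM(S, n=50)

    def test_too_few_dyads(self):
        cfg = SimulationConfig(n_dyads=4, seed=1)
        with pytest.raises(InsufficientRowsError):
            fit_apim(simulate_dyads(cfg), cfg.apim_spec())

    def test_multiplier_option_changes_chi_square_scale(self, qol_summary):
        spec_n = APIMSpec("depression", "qol", chi_square_multiplier="n")
        model = APIM.from_moments(qol_summary, spec_n)
        assert model.spec.multiplier(model.n) == 180
        spec_n1 = APIMSpec("depression", "qol")
        assert APIM.from_moments(qol_summary, spec_n1).spec.multiplier(180) == 179
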