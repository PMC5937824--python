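"""Equality-constrained APIM fits and chi-square difference tests.

The saturated APIM fits the sample covariance exactly (chi^2 = 0, df = 0),
so any question about *equality* of effects becomes a nested-model test:
refit with one equality imposed — e.g. equal actor effects a_m = a_f — and
measure how much the ML fit worsens,

    chi2_diff = chi2_constrained - chi2_unconstrained
    df_diff   = df_constrained  - df_unconstrained  (= 1 here),

referring chi2_diff to a chi-square distribution on df_diff.  A
significant result means the constrained pair of effects cannot be equal.

Three constraint kinds cover the standard questions about a dyad:

``actor_equal``      a_m = a_f    (is the actor effect the same for both roles?)
``partner_equal``    p_mf = p_fm  (is the partner effect the same?)
``actor_eq_partner`` a = p within one role's outcome equation
                     (is the actor effect larger than the partner effect?)

Each can be imposed on the unstandardized slopes (default, standard SEM
practice) or on the standardized coefficients — the distinction matters
whenever the two roles' predictor or outcome SDs differ, so both are
offered and labelled.

Unstandardized constraints are fitted by quasi-Newton minimisation of a
*concentrated* ML objective: for any slope matrix B the optimal exogenous
covariance is the sample predictor covariance and the optimal residual
covariance is the empirical residual covariance psi(B) = [-B I] S [-B I]',
leaving F(B) = ln|psi(B)| - ln|S_Y.X| over the three free slopes (an exact
reparameterization, not a penalty).  Standardized constraints couple the
slopes to the residual variances, so there the full 9-parameter vector is
optimised with a log-Cholesky covariance parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .apim import (
    APIM,
    APIMError,
    APIMParameters,
    APIMResults,
    APIMSpec,
    expected_information,
    f_ml,
    fit_apim,
    model_implied_sigma,
    sigma_derivatives,
)
from .dyad_data import DyadTable, MomentSummary

__all__ = [
    "ConstraintSpec",
    "ConstraintTestResult",
    "ConstraintError",
    "NonConvergenceError",
    "fit_constrained",
    "chisq_difference",
    "run_all_equality_tests",
]

KINDS = ("actor_equal", "partner_equal", "actor_eq_partner")
SCALES = ("unstandardized", "standardized")

#: clamp window for tiny negative chi-square differences (pure numerics)
NEG_CLAMP = 1e-6


class ConstraintError(APIMError):
    pass


class NonConvergenceError(ConstraintError):
    pass


@dataclass
class ConstraintSpec:
    """One equality constraint (df gain 1).

    ``role`` selects the outcome equation for ``actor_eq_partner`` and is
    either of the model's two role labels (or the shorthand "m"/"f" for
    the first/second role).  ``scale`` says whether the equality holds for
    the unstandardized slopes or the standardized coefficients.
    """

    kind: str
    role: str | None = None
    scale: str = "unstandardized"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConstraintError(f"unknown constraint kind {self.kind!r}")
        if self.scale not in SCALES:
            raise ConstraintError(f"unknown constraint scale {self.scale!r}")
        if self.kind == "actor_eq_partner" and self.role is None:
            raise ConstraintError("actor_eq_partner requires a role")

    def role_index(self, roles: tuple[str, str]) -> int:
        if self.role in (roles[0], "m", 0):
            return 0
        if self.role in (roles[1], "f", 1):
            return 1
        raise ConstraintError(f"role {self.role!r} not one of {roles}")

    def label(self, roles: tuple[str, str]) -> str:
        if self.kind == "actor_eq_partner":
            return f"actor_vs_partner_{roles[self.role_index(roles)]}"
        return self.kind


@dataclass
class ConstraintTestResult:
    """Chi-square difference test of a constrained vs unconstrained APIM."""

    label: str
    chi_sq_diff: float
    df_diff: int
    p: float
    constrained_fit: APIMResults
    unconstrained_fit: APIMResults

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


# ---------------------------------------------------------------------------
# slope-matrix builders (B = [[a_m, p_mf], [p_fm, a_f]])
# ---------------------------------------------------------------------------

def _b_builder_unstd(kind: str, role_idx: int | None) -> Callable[[np.ndarray], np.ndarray]:
    if kind == "actor_equal":
        return lambda s: np.array([[s[0], s[1]], [s[2], s[0]]])
    if kind == "partner_equal":
        return lambda s: np.array([[s[0], s[2]], [s[2], s[1]]])
    if role_idx == 0:  # a_m = p_mf (male-outcome equation)
        return lambda s: np.array([[s[0], s[0]], [s[1], s[2]]])
    return lambda s: np.array([[s[0], s[1]], [s[2], s[2]]])  # a_f = p_fm


def _b_start_unstd(kind: str, role_idx: int | None, B0: np.ndarray) -> np.ndarray:
    a_m, p_mf, p_fm, a_f = B0[0, 0], B0[0, 1], B0[1, 0], B0[1, 1]
    if kind == "actor_equal":
        return np.array([(a_m + a_f) / 2, p_mf, p_fm])
    if kind == "partner_equal":
        return np.array([a_m, a_f, (p_mf + p_fm) / 2])
    if role_idx == 0:
        return np.array([(a_m + p_mf) / 2, p_fm, a_f])
    return np.array([a_m, p_mf, (a_f + p_fm) / 2])


# ---------------------------------------------------------------------------
# standardized-scale parameterization
# ---------------------------------------------------------------------------

def _chol_to_cov(u: np.ndarray) -> np.ndarray:
    """log-Cholesky (u1, u2, u3) -> SPD 2x2 matrix."""
    L = np.array([[np.exp(u[0]), 0.0], [u[1], np.exp(u[2])]])
    return L @ L.T


def _cov_to_chol(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _solve_constrained_slope(beta: float, var_pred: float, phi12: float,
                             other_slope: float, other_var: float,
                             resid_var: float) -> float:
    """Slope s with standardized coefficient beta in an outcome equation
    Y = s X + other_slope X_other + E.

    From s sd(X) = beta sd(Y) with sd(Y)^2 = s^2 var_pred
    + 2 s other_slope phi12 + other_slope^2 other_var + resid_var:

        (1 - beta^2) var_pred s^2 - 2 beta^2 other_slope phi12 s
            - beta^2 (other_slope^2 other_var + resid_var) = 0 .

    For |beta| < 1 the two roots have opposite signs; the one matching
    sign(beta) is the constrained slope.
    """
    if beta == 0.0:
        return 0.0
    A = (1.0 - beta**2) * var_pred
    Bq = -2.0 * beta**2 * other_slope * phi12
    C = -(beta**2) * (other_slope**2 * other_var + resid_var)
    disc = Bq * Bq - 4.0 * A * C
    if disc < 0:  # pragma: no cover - disc >= 0 whenever |beta| < 1
        raise ConstraintError("no real constrained slope")
    root = np.sqrt(disc)
    s1 = (-Bq + root) / (2.0 * A)
    s2 = (-Bq - root) / (2.0 * A)
    return s1 if np.sign(s1) == np.sign(beta) else s2


def _theta_builder_std(kind: str, role_idx: int | None) -> Callable[[np.ndarray], np.ndarray]:
    """free (9,) -> structural theta (10,) for standardized-scale constraints.

    free = (3 slope-block parameters, 3 log-Cholesky phi, 3 log-Cholesky psi).
    """

    def build(free: np.ndarray) -> np.ndarray:
        phi = _chol_to_cov(free[3:6])
        psi = _chol_to_cov(free[6:9])
        f0, f1, f2 = free[0], free[1], free[2]
        if kind == "actor_equal":
            beta, p_mf, p_fm = f0, f1, f2
            a_m = _solve_constrained_slope(beta, phi[0, 0], phi[0, 1],
                                           p_mf, phi[1, 1], psi[0, 0])
            a_f = _solve_constrained_slope(beta, phi[1, 1], phi[0, 1],
                                           p_fm, phi[0, 0], psi[1, 1])
        elif kind == "partner_equal":
            a_m, a_f, beta = f0, f1, f2
            p_mf = _solve_constrained_slope(beta, phi[1, 1], phi[0, 1],
                                            a_m, phi[0, 0], psi[0, 0])
            p_fm = _solve_constrained_slope(beta, phi[0, 0], phi[0, 1],
                                            a_f, phi[1, 1], psi[1, 1])
        elif role_idx == 0:
            # beta_actor_m = beta_partner_mf <=> a_m sd(X_m) = p_mf sd(X_f)
            a_m, p_fm, a_f = f0, f1, f2
            p_mf = a_m * np.sqrt(phi[0, 0] / phi[1, 1])
        else:
            a_m, p_mf, a_f = f0, f1, f2
            p_fm = a_f * np.sqrt(phi[1, 1] / phi[0, 0])
        return np.array([
            a_m, p_mf, p_fm, a_f,
            phi[0, 0], phi[0, 1], phi[1, 1],
            psi[0, 0], psi[0, 1], psi[1, 1],
        ])

    return build


def _start_std(kind: str, role_idx: int | None, fit0: APIMResults) -> np.ndarray:
    b = fit0.standardized
    B0 = fit0.params.slope_matrix
    if kind == "actor_equal":
        slopes = [np.clip((b["actor_m"] + b["actor_f"]) / 2, -0.99, 0.99),
                  B0[0, 1], B0[1, 0]]
    elif kind == "partner_equal":
        slopes = [B0[0, 0], B0[1, 1],
                  np.clip((b["partner_mf"] + b["partner_fm"]) / 2, -0.99, 0.99)]
    elif role_idx == 0:
        slopes = [(B0[0, 0] + B0[0, 1]) / 2, B0[1, 0], B0[1, 1]]
    else:
        slopes = [B0[0, 0], B0[0, 1], (B0[1, 1] + B0[1, 0]) / 2]
    return np.concatenate([
        slopes,
        _cov_to_chol(fit0.params.phi),
        _cov_to_chol(fit0.params.psi),
    ])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_MAXITER = 500
_GTOL = 1e-8
_N_STARTS = 3


def _minimize(fun, x0: np.ndarray, rng: np.random.Generator):
    """BFGS with jittered restarts; returns (x, f, converged, message)."""
    best = None
    x_start = x0
    for attempt in range(_N_STARTS):
        res = optimize.minimize(fun, x_start, method="BFGS",
                                options={"gtol": _GTOL, "maxiter": _MAXITER})
        gnorm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.inf
        ok = bool(res.success) or gnorm < 1e-6
        if best is None or res.fun < best[1]:
            best = (res.x, float(res.fun), ok, f"{res.message} (|grad| = {gnorm:.2e})")
        if ok:
            break
        x_start = x0 * (1.0 + 0.1 * rng.standard_normal(x0.size)) + 0.01 * rng.standard_normal(x0.size)
    return best


def fit_constrained(
    data: APIM | DyadTable | pd.DataFrame | MomentSummary,
    constraint: ConstraintSpec,
    spec: APIMSpec | None = None,
    seed: int = 0,
) -> APIMResults:
    """ML fit of the APIM with one equality constraint imposed (df = 1).

    ``data`` may be an :class:`~dyadkit.apim.APIM` model, a raw dyad table
    or a :class:`~dyadkit.dyad_data.MomentSummary`.  The constrained pair
    shares a single parameter by reparameterization.  Non-convergence is
    reported honestly via the results' ``converged`` flag (and the final
    gradient norm in ``optimizer_message``).
    """
    if isinstance(data, APIM):
        model = data
    elif isinstance(data, MomentSummary):
        model = APIM.from_moments(data, spec)
    else:
        model = APIM.from_dyad_table(data, spec)

    S = model.S
    n_star = model.spec.multiplier(model.n)
    role_idx = (constraint.role_index(model.spec.roles)
                if constraint.kind == "actor_eq_partner" else None)
    fit0 = model.fit()
    rng = np.random.default_rng(seed)

    if constraint.scale == "unstandardized":
        S_xx, S_yx, S_yy = S[:2, :2], S[2:, :2], S[2:, 2:]
        S_cond = S_yy - S_yx @ np.linalg.solve(S_xx, S_yx.T)
        _, logdet_cond = np.linalg.slogdet(S_cond)
        build_B = _b_builder_unstd(constraint.kind, role_idx)

        def objective(s: np.ndarray) -> float:
            B = build_B(s)
            psi = S_yy - B @ S_yx.T - S_yx @ B.T + B @ S_xx @ B.T
            sign, logdet = np.linalg.slogdet(psi)
            if sign <= 0:
                return 1e10
            return logdet - logdet_cond

        x0 = _b_start_unstd(constraint.kind, role_idx, fit0.params.slope_matrix)
        x_hat, f_min, ok, msg = _minimize(objective, x0, rng)
        B_hat = build_B(x_hat)
        psi_hat = S_yy - B_hat @ S_yx.T - S_yx @ B_hat.T + B_hat @ S_xx @ B_hat.T
        psi_hat = (psi_hat + psi_hat.T) / 2.0
        params = APIMParameters(
            a_m=B_hat[0, 0], p_mf=B_hat[0, 1], p_fm=B_hat[1, 0], a_f=B_hat[1, 1],
            phi=S_xx, psi=psi_hat,
        )
        # free vector for the information matrix: 3 slopes + raw covariances
        def theta_from_free(free: np.ndarray) -> np.ndarray:
            Bf = build_B(free[:3])
            return np.array([
                Bf[0, 0], Bf[0, 1], Bf[1, 0], Bf[1, 1],
                free[3], free[4], free[5], free[6], free[7], free[8],
            ])

        free_hat = np.concatenate([
            x_hat,
            [S_xx[0, 0], S_xx[0, 1], S_xx[1, 1],
             psi_hat[0, 0], psi_hat[0, 1], psi_hat[1, 1]],
        ])
    else:
        theta_from_free = _theta_builder_std(constraint.kind, role_idx)

        def objective(free: np.ndarray) -> float:
            if constraint.kind in ("actor_equal", "partner_equal"):
                beta = free[0] if constraint.kind == "actor_equal" else free[2]
                if abs(beta) >= 0.999999:
                    return 1e10 + beta**2
            try:
                sigma = model_implied_sigma(
                    APIMParameters.from_theta(theta_from_free(free))
                )
                return f_ml(S, sigma)
            except (APIMError, np.linalg.LinAlgError):
                return 1e10

        x0 = _start_std(constraint.kind, role_idx, fit0)
        free_hat, f_min, ok, msg = _minimize(objective, x0, rng)
        params = APIMParameters.from_theta(theta_from_free(free_hat))

    f_min = max(float(f_min), 0.0)
    cov_theta = _cov_theta_reduced(params, theta_from_free, free_hat, n_star)
    return APIMResults(
        model=model, params=params, cov_theta=cov_theta,
        fml=f_min, chi_square=n_star * f_min, df=1, converged=ok,
        optimizer_message=msg,
    )


def _cov_theta_reduced(
    params: APIMParameters,
    theta_from_free: Callable[[np.ndarray], np.ndarray],
    free_hat: np.ndarray,
    n_star: float,
) -> np.ndarray:
    """Covariance of the structural parameters under a reduced
    parameterization: J I_free^{-1} J' with J = d theta / d free."""
    q = free_hat.size
    theta_hat = theta_from_free(free_hat)
    J = np.zeros((theta_hat.size, q))
    for k in range(q):
        h = 1e-6 * max(1.0, abs(free_hat[k]))
        fp, fm = free_hat.copy(), free_hat.copy()
        fp[k] += h
        fm[k] -= h
        J[:, k] = (theta_from_free(fp) - theta_from_free(fm)) / (2.0 * h)
    struct_derivs = sigma_derivatives(params)
    sigma = model_implied_sigma(params)
    derivs_free = [
        sum(J[t, k] * struct_derivs[t] for t in range(theta_hat.size))
        for k in range(q)
    ]
    info_free = expected_information(sigma, derivs_free, n_star)
    cov_free = np.linalg.pinv(info_free)
    return J @ cov_free @ J.T


# ---------------------------------------------------------------------------
# chi-square difference
# ---------------------------------------------------------------------------

def chisq_difference(
    constrained: APIMResults, unconstrained: APIMResults, label: str | None = None
) -> ConstraintTestResult:
    """Chi-square difference test of nested APIM fits.

    Requires the same data (sample covariance and n) and the same
    chi-square multiplier.  Differences in [-1e-6, 0) are numerical noise
    and are clamped to 0; anything more negative indicates non-nested fits.
    """
    if constrained.n != unconstrained.n or not np.allclose(
        constrained.model.S, unconstrained.model.S, atol=1e-12
    ):
        raise ConstraintError("fits must be computed on the same data")
    if constrained.spec.chi_square_multiplier != unconstrained.spec.chi_square_multiplier:
        raise ConstraintError("fits must use the same chi-square multiplier")
    df_diff = constrained.df - unconstrained.df
    if df_diff <= 0:
        raise ConstraintError("constrained fit must have more df (nested models)")
    diff = constrained.chi_square - unconstrained.chi_square
    if diff < -NEG_CLAMP:
        raise ConstraintError(
            f"chi-square difference {diff:.3e} is negative beyond tolerance; "
            "fits are not nested"
        )
    diff = max(diff, 0.0)
    p = float(stats.chi2.sf(diff, df_diff))
    return ConstraintTestResult(
        label=label or "chisq_difference",
        chi_sq_diff=diff, df_diff=df_diff, p=p,
        constrained_fit=constrained, unconstrained_fit=unconstrained,
    )


def run_all_equality_tests(
    data: APIM | DyadTable | pd.DataFrame | MomentSummary,
    spec: APIMSpec | None = None,
    scale: str = "unstandardized",
    seed: int = 0,
) -> list[ConstraintTestResult]:
    """The four standard equality tests, in fixed order.

    1. actor_equal        (a_m = a_f)
    2. partner_equal      (p_mf = p_fm)
    3. actor_vs_partner for the first role's outcome  (a_m = p_mf)
    4. actor_vs_partner for the second role's outcome (a_f = p_fm)
    """
    if isinstance(data, APIM):
        model = data
    elif isinstance(data, MomentSummary):
        model = APIM.from_moments(data, spec)
    else:
        model = APIM.from_dyad_table(data, spec)
    unconstrained = model.fit()
    roles = model.spec.roles
    specs = [
        ConstraintSpec("actor_equal", scale=scale),
        ConstraintSpec("partner_equal", scale=scale),
        ConstraintSpec("actor_eq_partner", role=roles[0], scale=scale),
        ConstraintSpec("actor_eq_partner", role=roles[1], scale=scale),
    ]
    out = []
    for cs in specs:
        constrained = fit_constrained(model, cs, seed=seed)
        out.append(chisq_difference(constrained, unconstrained,
                                    label=cs.label(roles)))
    return out


def equality_tests_table(
    results: Sequence[ConstraintTestResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Flat table of constraint-test results with a decision column."""
    return pd.DataFrame([
        {
            "constraint": r.label,
            "chi_sq_diff": r.chi_sq_diff,
            "df": r.df_diff,
            "p": r.p,
            "significant": r.p < alpha,
            "converged": r.constrained_fit.converged,
        }
        for r in results
    ])
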