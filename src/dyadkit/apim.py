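"""Actor-partner interdependence model (APIM) for distinguishable dyads.

The model
---------
For a couple with distinguishable roles (here indexed m and f), one
predictor X per member (depression) and one outcome Y per member (quality
of life), the APIM is the pair of simultaneous linear equations

    Y_m = a_m X_m + p_mf X_f + E_m
    Y_f = a_f X_f + p_fm X_m + E_f

where ``a_m, a_f`` are *actor* effects (own predictor -> own outcome) and
``p_mf, p_fm`` are *partner* effects (partner's predictor -> own outcome;
``p_mf`` carries the f-member's predictor into the m-member's outcome).
Two covariances complete the model: ``phi``, the exogenous covariance of
(X_m, X_f) — partners' predictors may correlate through a compositional
effect — and ``psi``, the covariance of the residuals (E_m, E_f), the
non-independence left over after the paths.  The dyad, not the individual,
is the sampling unit, so n is the number of couples.

Estimation is by maximum-likelihood covariance-structure analysis: the
model-implied covariance Sigma(theta) over (X_m, X_f, Y_m, Y_f) is matched
to the sample covariance S by minimising the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p .

The unconstrained APIM is *saturated* (10 parameters, 10 distinct
moments): its estimates exist in closed form — each outcome regressed on
both predictors from the covariance matrix — F_ML = 0, chi^2 = 0, df = 0.
Constrained variants (see :mod:`dyadkit.constraints`) are fitted
numerically and compared by the chi-square difference test.

Means are treated as saturated and not modelled: the equations carry no
intercepts and every reported quantity is a function of the covariance
matrix alone.

Standard errors use the expected information of the ML problem with the
same multiplier as the chi-square statistic ((n-1) F_ML by default, the
Wishart convention; n F_ML optional).  Standardized-path SEs are
delta-method transforms of the unstandardized covariance and are reported
separately — the two conventions differ and must not be conflated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dyad_data import (
    DyadTable,
    InsufficientRowsError,
    MomentSummary,
    NotPositiveSemidefiniteError,
    moments_from_table,
)

__all__ = [
    "APIMSpec",
    "APIMParameters",
    "APIM",
    "APIMResults",
    "APIMError",
    "CollinearPredictorsError",
    "SingularMatrixError",
    "model_implied_sigma",
    "f_ml",
    "fit_apim",
    "standardized_solution",
    "wald_tests",
    "PATHS",
]

#: canonical path labels, in reporting order
PATHS = ("actor_m", "actor_f", "partner_mf", "partner_fm")

#: index of each path's slope in the structural parameter vector theta
_THETA_NAMES = (
    "a_m", "p_mf", "p_fm", "a_f",
    "phi_mm", "phi_mf", "phi_ff",
    "psi_mm", "psi_mf", "psi_ff",
)
_PATH_THETA_INDEX = {"actor_m": 0, "partner_mf": 1, "partner_fm": 2, "actor_f": 3}


class APIMError(ValueError):
    pass


class CollinearPredictorsError(APIMError):
    pass


class SingularMatrixError(APIMError):
    pass


@dataclass
class APIMSpec:
    """What to fit: per-role predictor/outcome names and conventions.

    ``chi_square_multiplier`` selects chi^2 = (n-1) F_ML (``"n_minus_1"``,
    Wishart convention, default) or n F_ML (``"n"``).
    """

    x_var: str = "depression"
    y_var: str = "qol"
    roles: tuple[str, str] = ("male", "female")
    chi_square_multiplier: str = "n_minus_1"

    def __post_init__(self) -> None:
        if self.x_var == self.y_var:
            raise APIMError("predictor and outcome variable names must differ")
        if len(set(self.roles)) != 2:
            raise APIMError("roles must be two distinguishable labels")
        if self.chi_square_multiplier not in ("n_minus_1", "n"):
            raise APIMError("chi_square_multiplier must be 'n_minus_1' or 'n'")

    def multiplier(self, n: int) -> float:
        return float(n - 1 if self.chi_square_multiplier == "n_minus_1" else n)

    def variable_order(self) -> list[str]:
        r0, r1 = self.roles
        return [f"{self.x_var}_{r0}", f"{self.x_var}_{r1}",
                f"{self.y_var}_{r0}", f"{self.y_var}_{r1}"]


@dataclass
class APIMParameters:
    """Structural parameters: four slopes plus exogenous/residual covariances.

    ``phi`` is the 2x2 covariance of (X_m, X_f); ``psi`` the 2x2 residual
    covariance of (E_m, E_f).  The slope matrix B = [[a_m, p_mf],
    [p_fm, a_f]] maps (X_m, X_f) to the structural part of (Y_m, Y_f).
    """

    a_m: float
    a_f: float
    p_mf: float
    p_fm: float
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        for name, M in (("phi", self.phi), ("psi", self.psi)):
            if M.shape != (2, 2) or not np.allclose(M, M.T, atol=1e-10):
                raise APIMError(f"{name} must be a symmetric 2x2 matrix")
            if M[0, 0] <= 0 or M[1, 1] <= 0:
                raise APIMError(f"{name} must have positive diagonal")
            if abs(M[0, 1]) > np.sqrt(M[0, 0] * M[1, 1]) + 1e-10:
                raise APIMError(f"{name} implies |correlation| > 1")

    @property
    def slope_matrix(self) -> np.ndarray:
        return np.array([[self.a_m, self.p_mf], [self.p_fm, self.a_f]])

    def theta(self) -> np.ndarray:
        return np.array([
            self.a_m, self.p_mf, self.p_fm, self.a_f,
            self.phi[0, 0], self.phi[0, 1], self.phi[1, 1],
            self.psi[0, 0], self.psi[0, 1], self.psi[1, 1],
        ])

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "APIMParameters":
        t = np.asarray(theta, dtype=float)
        phi = np.array([[t[4], t[5]], [t[5], t[6]]])
        psi = np.array([[t[7], t[8]], [t[8], t[9]]])
        return cls(a_m=t[0], p_mf=t[1], p_fm=t[2], a_f=t[3], phi=phi, psi=psi)


def model_implied_sigma(params: APIMParameters) -> np.ndarray:
    """Model-implied 4x4 covariance over (X_m, X_f, Y_m, Y_f).

    Sigma_XX = phi; Sigma_YX = B phi; Sigma_YY = B phi B' + psi.
    """
    B = params.slope_matrix
    phi, psi = params.phi, params.psi
    top = np.hstack([phi, phi @ B.T])
    bottom = np.hstack([B @ phi, B @ phi @ B.T + psi])
    sigma = np.vstack([top, bottom])
    return (sigma + sigma.T) / 2.0


def f_ml(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML covariance-structure discrepancy.

    F = ln|sigma| + tr(S sigma^{-1}) - ln|S| - p; nonnegative, zero iff
    sigma = S.
    """
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_S, logdet_S = np.linalg.slogdet(S)
    if sign_s <= 0 or sign_S <= 0:
        raise SingularMatrixError("covariance matrices must be positive definite")
    return float(logdet_s + np.trace(np.linalg.solve(sigma, S)) - logdet_S - p)


# ---------------------------------------------------------------------------
# expected information
# ---------------------------------------------------------------------------

def _sym(i: int, j: int) -> np.ndarray:
    E = np.zeros((2, 2))
    E[i, j] = 1.0
    E[j, i] = 1.0
    return E


def sigma_derivatives(params: APIMParameters) -> list[np.ndarray]:
    """Analytic dSigma/dtheta for the 10 structural parameters.

    Sigma is quadratic in theta, so these are exact everywhere.
    """
    B = params.slope_matrix
    phi = params.phi
    derivs: list[np.ndarray] = []
    # slopes, theta order (a_m, p_mf, p_fm, a_f) = B entries (0,0),(0,1),(1,0),(1,1)
    for (k, l) in ((0, 0), (0, 1), (1, 0), (1, 1)):
        dB = np.zeros((2, 2))
        dB[k, l] = 1.0
        D = np.zeros((4, 4))
        dYX = dB @ phi
        D[2:, :2] = dYX
        D[:2, 2:] = dYX.T
        D[2:, 2:] = dB @ phi @ B.T + B @ phi @ dB.T
        derivs.append(D)
    # phi entries (0,0), (0,1), (1,1)
    for (i, j) in ((0, 0), (0, 1), (1, 1)):
        E = _sym(i, j)
        D = np.zeros((4, 4))
        D[:2, :2] = E
        D[2:, :2] = B @ E
        D[:2, 2:] = (B @ E).T
        D[2:, 2:] = B @ E @ B.T
        derivs.append(D)
    # psi entries
    for (i, j) in ((0, 0), (0, 1), (1, 1)):
        D = np.zeros((4, 4))
        D[2:, 2:] = _sym(i, j)
        derivs.append(D)
    return derivs


def expected_information(
    sigma: np.ndarray, derivs: Sequence[np.ndarray], n_star: float
) -> np.ndarray:
    """Expected (Fisher) information of the ML covariance-structure problem.

    I_ij = (n*/2) tr(Sigma^{-1} dSigma_i Sigma^{-1} dSigma_j), where n* is
    the chi-square multiplier (n-1 or n).
    """
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded upstream
        raise SingularMatrixError(str(e)) from e
    M = [sigma_inv @ D for D in derivs]
    q = len(M)
    info = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            info[i, j] = info[j, i] = 0.5 * n_star * np.trace(M[i] @ M[j])
    return info


# ---------------------------------------------------------------------------
# standardized solution
# ---------------------------------------------------------------------------

def _std_from_theta(theta: np.ndarray) -> dict[str, float]:
    """Standardized paths beta = slope * sd(predictor)/sd(outcome), with SDs
    from the model-implied covariance."""
    params = APIMParameters.from_theta(theta)
    sigma = model_implied_sigma(params)
    sd = np.sqrt(np.diag(sigma))  # (x_m, x_f, y_m, y_f)
    return {
        "actor_m": params.a_m * sd[0] / sd[2],
        "actor_f": params.a_f * sd[1] / sd[3],
        "partner_mf": params.p_mf * sd[1] / sd[2],
        "partner_fm": params.p_fm * sd[0] / sd[3],
    }


def _std_gradients(theta: np.ndarray, rel_h: float = 1e-6) -> dict[str, np.ndarray]:
    """Central-difference gradients of each standardized path wrt theta."""
    grads = {p: np.zeros(theta.size) for p in PATHS}
    for k in range(theta.size):
        h = rel_h * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        bp, bm = _std_from_theta(tp), _std_from_theta(tm)
        for p in PATHS:
            grads[p][k] = (bp[p] - bm[p]) / (2.0 * h)
    return grads


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

def _infer_spec(variables: Sequence[str]) -> APIMSpec | None:
    """APIMSpec from four role-suffixed names ordered (x_r0, x_r1, y_r0, y_r1)."""
    if len(variables) != 4 or any("_" not in v for v in variables):
        return None
    split = [v.rsplit("_", 1) for v in variables]
    (x0, r0), (x1, r1), (y0, r2), (y1, r3) = split
    if x0 == x1 and y0 == y1 and (r0, r1) == (r2, r3) and r0 != r1 and x0 != y0:
        return APIMSpec(x_var=x0, y_var=y0, roles=(r0, r1))
    return None


class APIM:
    """APIM for one predictor/outcome pair over distinguishable dyads.

    Construct from a raw :class:`~dyadkit.dyad_data.DyadTable` (or wide
    DataFrame) with :meth:`from_dyad_table`, or from published moments with
    :meth:`from_moments`; ``fit()`` returns :class:`APIMResults`.
    """

    def __init__(self, S: np.ndarray, n: int, spec: APIMSpec | None = None,
                 means: np.ndarray | None = None):
        self.spec = spec or APIMSpec()
        S = np.asarray(S, dtype=float)
        if S.shape != (4, 4):
            raise APIMError("S must be 4x4 over (X_m, X_f, Y_m, Y_f)")
        if not np.allclose(S, S.T, atol=1e-10):
            raise APIMError("S must be symmetric")
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise NotPositiveSemidefiniteError(
                "sample covariance must be positive definite"
            )
        r_xx = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        if abs(r_xx) >= 1.0 - 1e-10:
            raise CollinearPredictorsError(
                f"predictors are collinear (|r| = {abs(r_xx):.12f})"
            )
        self.S = (S + S.T) / 2.0
        self.n = int(n)
        self.means = None if means is None else np.asarray(means, dtype=float)
        self.variable_order = self.spec.variable_order()

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_dyad_table(
        cls, data: DyadTable | pd.DataFrame, spec: APIMSpec | None = None
    ) -> "APIM":
        spec = spec or APIMSpec()
        table = data if isinstance(data, DyadTable) else DyadTable(data, roles=spec.roles)
        cols = spec.variable_order()
        summary = moments_from_table(table, cols)
        if summary.n < 5:
            raise InsufficientRowsError(
                f"need >= 5 complete dyads, got {summary.n}"
            )
        return cls(summary.covariance(), summary.n, spec, means=summary.means)

    @classmethod
    def from_moments(
        cls, summary: MomentSummary, spec: APIMSpec | None = None
    ) -> "APIM":
        """Fit-ready model from sufficient statistics.

        ``summary`` must hold the four variables of ``spec`` (in any
        order); the covariance is assembled as D R D.  With no ``spec``
        and exactly four ``<var>_<role>`` variables ordered
        (x_r0, x_r1, y_r0, y_r1), the spec is inferred from the names.
        """
        spec = spec or _infer_spec(summary.variables) or APIMSpec()
        sub = summary.subset(spec.variable_order())
        return cls(sub.covariance(), sub.n, spec, means=sub.means)

    # -- estimation ----------------------------------------------------------

    def fit(self) -> "APIMResults":
        """Closed-form saturated ML fit.

        Each outcome is regressed on both predictors from the covariance
        matrix; phi is the sample predictor covariance and psi the residual
        covariance of the two equations.  The model reproduces S exactly,
        so F_ML = 0, chi^2 = 0, df = 0.
        """
        S = self.S
        S_xx, S_yx, S_yy = S[:2, :2], S[2:, :2], S[2:, 2:]
        B = np.linalg.solve(S_xx, S_yx.T).T
        psi = S_yy - B @ S_xx @ B.T
        psi = (psi + psi.T) / 2.0
        params = APIMParameters(
            a_m=B[0, 0], p_mf=B[0, 1], p_fm=B[1, 0], a_f=B[1, 1],
            phi=S_xx, psi=psi,
        )
        theta = params.theta()
        n_star = self.spec.multiplier(self.n)
        sigma = model_implied_sigma(params)
        info = expected_information(sigma, sigma_derivatives(params), n_star)
        try:
            cov_theta = np.linalg.inv(info)
        except np.linalg.LinAlgError as e:
            raise SingularMatrixError("singular information matrix") from e
        fval = f_ml(S, sigma)
        return APIMResults(
            model=self, params=params, cov_theta=cov_theta,
            fml=fval, chi_square=n_star * fval, df=0, converged=True,
        )

    def fit_constrained(self, constraint) -> "APIMResults":
        """Fit with one equality constraint (see :mod:`dyadkit.constraints`)."""
        from .constraints import fit_constrained

        return fit_constrained(self, constraint)


class APIMResults:
    """Estimates, uncertainties and fit statistics of one APIM fit.

    Attributes
    ----------
    params : APIMParameters
    paths : dict
        Unstandardized slope per path (keys ``actor_m``, ``actor_f``,
        ``partner_mf``, ``partner_fm``).
    standardized : dict
        Standardized coefficients beta (slope scaled by model-implied SDs).
    bse, bse_standardized : dict
        Expected-information SEs of the slopes and delta-method SEs of the
        standardized coefficients.
    zvalues, pvalues : dict
        Signed Wald z = estimate/SE (unstandardized) and two-sided normal p.
    fml, chi_square, df, converged, n : fit statistics.
    """

    def __init__(self, model: APIM, params: APIMParameters,
                 cov_theta: np.ndarray | None, fml: float, chi_square: float,
                 df: int, converged: bool, optimizer_message: str = ""):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.n = model.n
        self.fml = float(fml)
        self.chi_square = max(float(chi_square), 0.0)
        self.df = int(df)
        self.converged = bool(converged)
        self.optimizer_message = optimizer_message
        self.cov_theta = cov_theta

        theta = params.theta()
        self.theta = theta
        self.paths: dict[str, float] = {
            p: float(theta[_PATH_THETA_INDEX[p]]) for p in PATHS
        }
        self.standardized: dict[str, float] = {
            p: float(v) for p, v in _std_from_theta(theta).items()
        }
        for p, b in self.standardized.items():
            if abs(b) > 1.0:
                warnings.warn(
                    f"standardized coefficient |beta| > 1 on path {p}: {b:.3f}",
                    stacklevel=2,
                )

        if cov_theta is not None:
            se_theta = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
            self.bse = {p: float(se_theta[_PATH_THETA_INDEX[p]]) for p in PATHS}
            grads = _std_gradients(theta)
            self.bse_standardized = {
                p: float(np.sqrt(max(g @ cov_theta @ g, 0.0)))
                for p, g in grads.items()
            }
        else:  # pragma: no cover - all fit routes supply cov_theta
            self.bse = {p: float("nan") for p in PATHS}
            self.bse_standardized = dict(self.bse)

        self.zvalues: dict[str, float] = {}
        self.pvalues: dict[str, float] = {}
        for p in PATHS:
            se = self.bse[p]
            z = self.paths[p] / se if se > 0 else float("nan")
            self.zvalues[p] = float(z)
            self.pvalues[p] = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")

    # -- derived -------------------------------------------------------------

    @property
    def implied_sigma(self) -> np.ndarray:
        return model_implied_sigma(self.params)

    @property
    def p_value_chi_square(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.chi_square, self.df))

    # -- presentation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "x_var": self.spec.x_var,
            "y_var": self.spec.y_var,
            "roles": list(self.spec.roles),
            "n": self.n,
            "paths": self.paths,
            "standardized": self.standardized,
            "se_unstandardized": self.bse,
            "se_standardized": self.bse_standardized,
            "wald_z": self.zvalues,
            "p_values": self.pvalues,
            "phi": self.params.phi.tolist(),
            "psi": self.params.psi.tolist(),
            "f_ml": self.fml,
            "chi_square": self.chi_square,
            "df": self.df,
            "chi_square_multiplier": self.spec.chi_square_multiplier,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def path_table(self) -> pd.DataFrame:
        """One row per path: estimate, beta, SEs, z, p."""
        rows = []
        r0, r1 = self.spec.roles
        desc = {
            "actor_m": f"{r0} actor",
            "actor_f": f"{r1} actor",
            "partner_mf": f"{r1} {self.spec.x_var} -> {r0} {self.spec.y_var}",
            "partner_fm": f"{r0} {self.spec.x_var} -> {r1} {self.spec.y_var}",
        }
        for p in PATHS:
            rows.append({
                "path": p,
                "effect": desc[p],
                "estimate": self.paths[p],
                "beta": self.standardized[p],
                "se": self.bse[p],
                "se_beta": self.bse_standardized[p],
                "z": self.zvalues[p],
                "p": self.pvalues[p],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            f"APIM ({self.spec.x_var} -> {self.spec.y_var}; "
            f"roles {self.spec.roles[0]}/{self.spec.roles[1]}; n = {self.n} dyads)\n"
            f"chi2 = {self.chi_square:.4f}, df = {self.df}, "
            f"p = {self.p_value_chi_square:.4f} "
            f"[{self.spec.chi_square_multiplier} multiplier]; "
            f"converged = {self.converged}\n"
        )
        tab = self.path_table()
        lines = [head, f"{'path':<12}{'est':>10}{'beta':>10}{'se':>9}"
                       f"{'se_beta':>9}{'z':>9}{'p':>10}"]
        for _, r in tab.iterrows():
            lines.append(
                f"{r['path']:<12}{r['estimate']:>10.4f}{r['beta']:>10.4f}"
                f"{r['se']:>9.4f}{r['se_beta']:>9.4f}{r['z']:>9.3f}"
                f"{r['p']:>10.4g}"
            )
        rphi = self.params.phi[0, 1] / np.sqrt(self.params.phi[0, 0] * self.params.phi[1, 1])
        rpsi = self.params.psi[0, 1] / np.sqrt(self.params.psi[0, 0] * self.params.psi[1, 1])
        lines.append(
            f"predictor correlation r = {rphi:.3f}; residual correlation r = {rpsi:.3f}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_apim(
    data: DyadTable | pd.DataFrame | MomentSummary, spec: APIMSpec | None = None
) -> APIMResults:
    """Fit the unconstrained (saturated) APIM to raw dyads or moments."""
    if isinstance(data, MomentSummary):
        return APIM.from_moments(data, spec).fit()
    return APIM.from_dyad_table(data, spec).fit()


def standardized_solution(fit: APIMResults) -> dict[str, float]:
    """Standardized path coefficients of a converged fit."""
    if not fit.converged:
        raise APIMError("standardized solution requires a converged fit")
    return dict(fit.standardized)


def wald_tests(fit: APIMResults) -> dict[str, tuple[float, float, float]]:
    """Per-path (SE, z, two-sided p) for the unstandardized slopes."""
    if not fit.converged:
        raise APIMError("Wald tests require a converged fit")
    return {p: (fit.bse[p], fit.zvalues[p], fit.pvalues[p]) for p in PATHS}
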