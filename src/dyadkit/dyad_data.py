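"""Data model and I/O for distinguishable-dyad datasets.

Two containers cover every analysis in the package:

``DyadTable``
    Wide, one-row-per-couple data with role-suffixed columns
    (``depression_male``, ``qol_female``, ...).  The dyad — not the
    individual — is the sampling unit, so the table is the canonical raw
    input for all model fitting.

``MomentSummary``
    Means, sample SDs, a correlation matrix and n.  These are sufficient
    statistics for every covariance-structure computation here, which is
    what makes published summary tables a first-class input: a study whose
    raw data were never deposited can still be re-analysed from its printed
    moments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DyadTable",
    "MomentSummary",
    "DyadDataError",
    "MissingColumnError",
    "DuplicateDyadError",
    "NonNumericDataError",
    "InsufficientRowsError",
    "ZeroVarianceError",
    "NotPositiveSemidefiniteError",
    "read_dyad_table",
    "moments_from_table",
    "covariance_from_summary",
    "repair_correlations",
    "long_to_wide",
]

#: smallest admissible eigenvalue of a correlation matrix before it is
#: declared indefinite (published matrices rounded to 2 dp sit near zero).
PSD_TOL = 1e-8


class DyadDataError(ValueError):
    """Base class for dyad-data validation problems."""


class MissingColumnError(DyadDataError):
    pass


class DuplicateDyadError(DyadDataError):
    pass


class NonNumericDataError(DyadDataError):
    pass


class InsufficientRowsError(DyadDataError):
    pass


class ZeroVarianceError(DyadDataError):
    pass


class NotPositiveSemidefiniteError(DyadDataError):
    pass


@dataclass
class DyadTable:
    """Wide one-row-per-dyad dataset with two distinguishable roles.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per couple. Must contain ``id_col`` with unique values;
        analysis variables are named ``<variable>_<role>``.
    roles : tuple of str
        The two distinguishable role labels, e.g. ``("male", "female")``.
        Designs with indistinguishable members are rejected.
    id_col : str
        Name of the dyad identifier column.
    """

    data: pd.DataFrame
    roles: tuple[str, str] = ("male", "female")
    id_col: str = "dyad_id"

    def __post_init__(self) -> None:
        roles = tuple(self.roles)
        if len(roles) != 2 or roles[0] == roles[1]:
            raise DyadDataError(
                "dyads must have exactly two distinguishable roles, got "
                f"{roles!r}"
            )
        self.roles = roles
        if self.id_col not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, self.id_col, np.arange(1, len(self.data) + 1))
        dupes = self.data[self.id_col][self.data[self.id_col].duplicated()]
        if len(dupes):
            raise DuplicateDyadError(
                f"duplicated dyad_id values: {sorted(set(dupes))[:5]}"
            )

    @property
    def n_dyads(self) -> int:
        return len(self.data)

    def role_columns(self, variable: str) -> tuple[str, str]:
        """Column names for ``variable`` in role order."""
        cols = tuple(f"{variable}_{r}" for r in self.roles)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise MissingColumnError(f"missing columns: {missing}")
        return cols

    def columns_for(self, variables: Sequence[str]) -> list[str]:
        """Expand per-role variable names to concrete columns."""
        out: list[str] = []
        for v in variables:
            out.extend(self.role_columns(v))
        return out

    def complete_cases(self, columns: Sequence[str]) -> pd.DataFrame:
        """Listwise-complete rows on ``columns`` (values as float)."""
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise MissingColumnError(f"missing columns: {missing}")
        sub = self.data.loc[:, list(columns)].astype(float)
        return sub.dropna()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_dyad_table(
    path: str | Path,
    role_labels: tuple[str, str] = ("male", "female"),
    id_col: str = "dyad_id",
    required: Sequence[str] | None = None,
    **csv_kwargs,
) -> DyadTable:
    """Read a wide dyad CSV (RFC 4180, header row) into a ``DyadTable``.

    ``required`` lists per-role variable names that must be present for
    both roles; absence raises :class:`MissingColumnError`.  Cells that are
    present but not numeric raise :class:`NonNumericDataError` with the
    offending row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path, **csv_kwargs)
    if required:
        need = [f"{v}_{r}" for v in required for r in role_labels]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise MissingColumnError(f"missing columns: {missing}")
    value_cols = [c for c in df.columns if c != id_col]
    bad_rows: dict[str, list[int]] = {}
    for c in value_cols:
        if df[c].dtype == object:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[coerced.isna() & df[c].notna()]
            if len(bad):
                bad_rows[c] = [int(i) + 1 for i in bad]
            df[c] = coerced
    if bad_rows:
        raise NonNumericDataError(f"non-numeric cells (column: rows): {bad_rows}")
    return DyadTable(df, roles=tuple(role_labels), id_col=id_col)


def long_to_wide(
    df: pd.DataFrame,
    dyad_col: str = "dyad_id",
    role_col: str = "role",
    value_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pivot person-per-row (long) data to the canonical wide layout.

    The result has columns ``<value>_<role>``; the long format itself is
    never a fitting input.
    """
    if value_cols is None:
        value_cols = [c for c in df.columns if c not in (dyad_col, role_col)]
    wide = df.pivot(index=dyad_col, columns=role_col, values=list(value_cols))
    wide.columns = [f"{var}_{role}" for var, role in wide.columns]
    return wide.reset_index()


@dataclass
class MomentSummary:
    """Means, SDs, correlations and n — sufficient statistics for fitting.

    Invariants are enforced at construction: the correlation matrix must be
    symmetric with unit diagonal and entries in [-1, 1], SDs strictly
    positive, n >= p + 1, and the smallest eigenvalue of the correlation
    matrix must exceed ``-PSD_TOL`` (matrices printed to 2 decimals can be
    very slightly indefinite; anything worse is a data error — see
    :func:`repair_correlations` for an explicit, opt-in fix).
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    correlations: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.variables = list(self.variables)
        p = len(self.variables)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise DyadDataError("means/sds length must match variables")
        if self.correlations.shape != (p, p):
            raise DyadDataError("correlation matrix shape must match variables")
        if not np.all(self.sds > 0):
            raise ZeroVarianceError("all SDs must be strictly positive")
        if not np.allclose(self.correlations, self.correlations.T, atol=1e-12):
            raise DyadDataError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlations), 1.0, atol=1e-12):
            raise DyadDataError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.correlations) > 1 + 1e-12):
            raise DyadDataError("correlations must lie in [-1, 1]")
        if self.n < p + 1:
            raise InsufficientRowsError(f"need n >= p + 1 = {p + 1}, got n = {self.n}")
        eigmin = float(np.linalg.eigvalsh(self.correlations)[0])
        if eigmin < -PSD_TOL:
            raise NotPositiveSemidefiniteError(
                f"correlation matrix indefinite (min eigenvalue {eigmin:.3e}); "
                "see repair_correlations() for an explicit repair"
            )

    # -- derived quantities -------------------------------------------------

    def covariance(self) -> np.ndarray:
        """Implied covariance S = D R D with D = diag(sds)."""
        return covariance_from_summary(self)

    def subset(self, variables: Sequence[str]) -> "MomentSummary":
        idx = [self.variables.index(v) for v in variables]
        return MomentSummary(
            variables=list(variables),
            means=self.means[idx],
            sds=self.sds[idx],
            correlations=self.correlations[np.ix_(idx, idx)],
            n=self.n,
        )

    # -- JSON round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "correlations": self.correlations.tolist(),
            "n": int(self.n),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "MomentSummary":
        return cls(
            variables=d["variables"],
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            correlations=np.asarray(d["correlations"], dtype=float),
            n=int(d["n"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MomentSummary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def covariance_from_summary(
    summary: MomentSummary, repair: bool = False
) -> np.ndarray:
    """Covariance matrix S = D R D from a :class:`MomentSummary`.

    With ``repair=True`` a slightly indefinite correlation matrix is first
    projected to the PSD cone (eigenvalue clipping + re-scaling to unit
    diagonal); off by default so rounded published matrices are never
    silently altered.
    """
    R = summary.correlations
    eigmin = float(np.linalg.eigvalsh(R)[0])
    if eigmin < -PSD_TOL:
        if not repair:  # MomentSummary validation normally catches this first
            raise NotPositiveSemidefiniteError(
                f"correlation matrix indefinite (min eigenvalue {eigmin:.3e})"
            )
        R = repair_correlations(R)
    D = np.diag(summary.sds)
    S = D @ R @ D
    return (S + S.T) / 2.0


def repair_correlations(R: np.ndarray) -> np.ndarray:
    """Project a near-correlation matrix to the PSD cone.

    Eigenvalues are clipped at zero and the result re-scaled to unit
    diagonal.  One clipping pass suffices at the distance from PSD that
    2-dp rounding induces; the output is validated and returned.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, 0.0, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.clip(np.diag(A), 1e-300, None))
    out = A / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def moments_from_table(
    data: DyadTable | pd.DataFrame, variables: Sequence[str]
) -> MomentSummary:
    """Sample moments (mean, SD with n-1 denominator, Pearson r) after
    listwise deletion on ``variables``.

    ``variables`` are concrete column names (already role-suffixed).
    """
    df = data.data if isinstance(data, DyadTable) else data
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise MissingColumnError(f"missing columns: {missing}")
    sub = df.loc[:, list(variables)].astype(float).dropna()
    n = len(sub)
    if n < 2:
        raise InsufficientRowsError(f"need >= 2 complete rows, got {n}")
    X = sub.to_numpy()
    sds = X.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sds) if s == 0]
    if zero:
        raise ZeroVarianceError(f"zero-variance variables: {zero}")
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return MomentSummary(
        variables=list(variables),
        means=X.mean(axis=0),
        sds=sds,
        correlations=R,
        n=n,
    )
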