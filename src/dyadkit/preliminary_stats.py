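"""Preliminary dyadic analyses: paired comparisons, McNemar, correlations,
Cronbach's alpha.

Members of a couple are paired observations, so male-female comparisons of
means use the paired t statistic.  Because the paired t depends on the data
only through (means, SDs, within-pair correlation, n), it can be computed
either from raw vectors or from published summary moments — the two routes
agree exactly, which is what lets printed tables be re-analysed.  All tests
are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dyad_data import (
    DyadTable,
    InsufficientRowsError,
    MissingColumnError,
    ZeroVarianceError,
)

__all__ = [
    "PairedComparison",
    "CorrelationReport",
    "McNemarResult",
    "paired_t_from_summary",
    "paired_t_raw",
    "mcnemar_test",
    "correlation_report",
    "cronbach_alpha",
    "DEFAULT_STAR_LEVELS",
]

#: conventional significance stars: *, **, *** at these two-sided p levels
DEFAULT_STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class PairedComparison:
    """Paired t test of two correlated means (df = n - 1).

    ``t`` is signed with ``mean_b - mean_a``; ``infinite`` flags the
    degenerate case sd_diff = 0 with a nonzero mean difference.
    """

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    r_ab: float
    n: int
    t: float
    df: int
    p: float
    infinite: bool = False


def paired_t_from_summary(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    r_ab: float,
    n: int,
) -> PairedComparison:
    """Paired t test from summary moments.

    sd_diff = sqrt(sd_a^2 + sd_b^2 - 2 r sd_a sd_b);
    t = (mean_b - mean_a) / (sd_diff / sqrt(n)), df = n - 1.
    """
    if n < 2:
        raise InsufficientRowsError(f"need n >= 2, got {n}")
    if sd_a <= 0 or sd_b <= 0:
        raise ZeroVarianceError("paired t from summary requires positive SDs")
    if abs(r_ab) > 1:
        raise ValueError(f"invalid correlation r_ab = {r_ab}")
    var_diff = sd_a**2 + sd_b**2 - 2.0 * r_ab * sd_a * sd_b
    sd_diff = math.sqrt(max(var_diff, 0.0))
    diff = mean_b - mean_a
    df = n - 1
    if sd_diff == 0.0:
        if diff == 0.0:
            t, p, infinite = 0.0, 1.0, False
        else:
            t = math.copysign(math.inf, diff)
            p, infinite = 0.0, True
    else:
        t = diff / (sd_diff / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df))
        infinite = False
    return PairedComparison(
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b, r_ab=r_ab,
        n=n, t=t, df=df, p=p, infinite=infinite,
    )


def paired_t_raw(values_a: Sequence[float], values_b: Sequence[float]) -> PairedComparison:
    """Paired t test from raw paired vectors (listwise deletion).

    Exactly equals :func:`paired_t_from_summary` applied to the sample
    moments of the two vectors.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise InsufficientRowsError(f"need >= 2 complete pairs, got {n}")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a > 0 and sd_b > 0:
        r = float(np.corrcoef(a, b)[0, 1])
        return paired_t_from_summary(float(a.mean()), sd_a, float(b.mean()), sd_b, r, n)
    # constant column(s): fall back to the difference vector directly
    d = b - a
    sd_d = float(d.std(ddof=1))
    md = float(d.mean())
    df = n - 1
    if sd_d == 0.0:
        t = 0.0 if md == 0.0 else math.copysign(math.inf, md)
        p = 1.0 if md == 0.0 else 0.0
        infinite = md != 0.0
    else:
        t = md / (sd_d / math.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df))
        infinite = False
    return PairedComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=sd_a, sd_b=sd_b, r_ab=math.nan, n=n, t=t, df=df, p=p,
        infinite=infinite,
    )


class McNemarResult(NamedTuple):
    chi_square: float
    df: int
    p: float


def mcnemar_test(
    discordant_b: int, discordant_c: int, continuity: bool = False
) -> McNemarResult:
    """McNemar test for paired binary outcomes from the discordant counts.

    Without correction chi^2 = (b - c)^2 / (b + c); with the continuity
    correction (|b - c| - 1)^2 / (b + c), floored at 0.  b + c = 0 yields
    chi^2 = 0, p = 1 by convention.  No correction is the default: matched
    categorical comparisons with b = c then give exactly chi^2 = 0.
    """
    b, c = discordant_b, discordant_c
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return McNemarResult(0.0, 1, 1.0)
    if continuity:
        num = max(abs(b - c) - 1.0, 0.0) ** 2
    else:
        num = float(b - c) ** 2
    chi2 = num / (b + c)
    return McNemarResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix with two-sided p values and star annotations."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int
    star_levels: tuple[float, ...] = DEFAULT_STAR_LEVELS


def _stars(p: float, levels: Sequence[float]) -> str:
    return "*" * sum(p < lv for lv in sorted(levels, reverse=True))


def correlation_report(
    data: DyadTable | pd.DataFrame,
    variables: Sequence[str],
    star_levels: Sequence[float] = DEFAULT_STAR_LEVELS,
) -> CorrelationReport:
    """Pearson correlation matrix with significance stars.

    Two-sided p values come from the exact t transform
    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 df; |r| = 1 maps to p = 0.
    Stars are monotone in p at the configured levels.
    """
    df = data.data if isinstance(data, DyadTable) else data
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise MissingColumnError(f"missing columns: {missing}")
    sub = df.loc[:, list(variables)].astype(float).dropna()
    n = len(sub)
    if n < 3:
        raise InsufficientRowsError(f"need >= 3 complete rows, got {n}")
    X = sub.to_numpy()
    sds = X.std(axis=0, ddof=1)
    zero = [v for v, s in zip(variables, sds) if s == 0]
    if zero:
        raise ZeroVarianceError(f"zero-variance variables: {zero}")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    with np.errstate(divide="ignore"):
        tval = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-300, None))
    P = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    P[np.abs(R) >= 1.0 - 1e-15] = 0.0
    np.fill_diagonal(P, 0.0)
    vars_ = list(variables)
    r_df = pd.DataFrame(R, index=vars_, columns=vars_)
    p_df = pd.DataFrame(P, index=vars_, columns=vars_)
    stars = p_df.map(lambda p: _stars(p, star_levels))
    for v in vars_:
        stars.loc[v, v] = ""
    return CorrelationReport(r=r_df, p=p_df, stars=stars, n=n,
                             star_levels=tuple(star_levels))


def correlation_report_from_summary(
    summary,
    star_levels: Sequence[float] = DEFAULT_STAR_LEVELS,
) -> CorrelationReport:
    """Correlation report from a :class:`~dyadkit.dyad_data.MomentSummary`.

    Published correlation tables carry their own r values; p values are
    recovered from the t transform on n - 2 df, so a summary-mode report is
    exactly what the raw data would have produced.
    """
    R = np.asarray(summary.correlations, dtype=float)
    n = summary.n
    vars_ = list(summary.variables)
    with np.errstate(divide="ignore"):
        tval = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-300, None))
    P = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    P[np.abs(R) >= 1.0 - 1e-15] = 0.0
    np.fill_diagonal(P, 0.0)
    r_df = pd.DataFrame(R, index=vars_, columns=vars_)
    p_df = pd.DataFrame(P, index=vars_, columns=vars_)
    stars = p_df.map(lambda p: _stars(p, star_levels))
    for v in vars_:
        stars.loc[v, v] = ""
    return CorrelationReport(r=r_df, p=p_df, stars=stars, n=n,
                             star_levels=tuple(star_levels))


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) (1 - sum item variances / variance of total).

    ``items`` is respondents x items, complete rows only; variances use the
    n - 1 denominator.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientRowsError("need >= 2 respondents and >= 2 items")
    if np.isnan(X).any():
        raise ValueError("cronbach_alpha requires complete rows")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroVarianceError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
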