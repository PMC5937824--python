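"""Scoring for the two questionnaires used in the dyadic analysis.

PHQ-9
    Nine depression items rated 0 (not at all) to 3 (nearly every day);
    the total is the plain item sum, range 0-27, higher = more depressive
    symptoms.  With a configurable allowance for missing items the total is
    prorated (sum x 9 / answered).

FertiQoL core
    24 fertility-specific quality-of-life items rated 0-4, grouped into
    four named 6-item subscales (Emotional, Mind/Body, Relational, Social).
    Each subscale is the mean of its answered items rescaled to 0-100
    (x 25); the core total is the mean over *all* answered items x 25 —
    not the mean of the four subscale scores, which differs whenever
    missingness is unequal across subscales.  Higher = better QoL.

The scorer consumes pre-oriented items (higher response = better QoL /
more severe depression as appropriate for each instrument).  The official
FertiQoL form contains reverse-keyed items whose keying varies by
distribution; callers whose data are raw can pass an explicit
``reverse_key`` mask and the scorer will flip those items (v -> 4 - v)
before scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemResponses",
    "InstrumentScores",
    "InstrumentError",
    "WrongItemCountError",
    "ItemOutOfRangeError",
    "TooManyMissingError",
    "score_phq9",
    "score_fertiqol_core",
    "score_table",
    "PHQ9_ITEMS",
    "PHQ9_RANGE",
    "FERTIQOL_ITEMS",
    "FERTIQOL_RANGE",
    "FERTIQOL_SUBSCALES",
]

PHQ9_ITEMS = 9
PHQ9_RANGE = (0, 3)
FERTIQOL_ITEMS = 24
FERTIQOL_RANGE = (0, 4)
#: item positions (0-based) per subscale in the canonical 24-item order
FERTIQOL_SUBSCALES: Mapping[str, range] = {
    "Emotional": range(0, 6),
    "Mind/Body": range(6, 12),
    "Relational": range(12, 18),
    "Social": range(18, 24),
}

_SPEC = {
    "phq9": (PHQ9_ITEMS, PHQ9_RANGE),
    "fertiqol_core": (FERTIQOL_ITEMS, FERTIQOL_RANGE),
}


class InstrumentError(ValueError):
    """Base class for questionnaire validation failures."""


class WrongItemCountError(InstrumentError):
    pass


class ItemOutOfRangeError(InstrumentError):
    pass


class TooManyMissingError(InstrumentError):
    pass


def _as_value(v) -> float:
    """Normalise a raw cell to float, mapping None/NaN to nan."""
    if v is None:
        return math.nan
    f = float(v)
    return f


@dataclass
class ItemResponses:
    """Validated item-level responses for one respondent.

    ``values`` holds one entry per item; missing answers are explicit
    (``None`` or NaN), never silently coerced.
    """

    instrument_id: str
    values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.instrument_id not in _SPEC:
            raise InstrumentError(f"unknown instrument {self.instrument_id!r}")
        n_items, (lo, hi) = _SPEC[self.instrument_id]
        vals = [_as_value(v) for v in self.values]
        if len(vals) != n_items:
            raise WrongItemCountError(
                f"{self.instrument_id} expects {n_items} items, got {len(vals)}"
            )
        for i, v in enumerate(vals):
            if math.isnan(v):
                continue
            if not (lo <= v <= hi) or v != int(v):
                raise ItemOutOfRangeError(
                    f"item {i + 1} = {v!r} outside integer range [{lo}, {hi}]"
                )
        self.values = vals

    @classmethod
    def phq9(cls, values: Sequence) -> "ItemResponses":
        return cls("phq9", list(values))

    @classmethod
    def fertiqol_core(cls, values: Sequence) -> "ItemResponses":
        return cls("fertiqol_core", list(values))

    @property
    def n_missing(self) -> int:
        return sum(math.isnan(v) for v in self.values)


@dataclass
class InstrumentScores:
    """Scored totals (and, for FertiQoL, the four 0-100 subscales)."""

    instrument_id: str
    total: float
    subscales: dict[str, float] | None
    n_missing: int


def score_phq9(responses: ItemResponses, max_missing: int = 0) -> InstrumentScores:
    """PHQ-9 depression total (0-27).

    With ``max_missing`` > 0 the total is prorated over answered items
    (sum x 9 / answered); beyond the allowance a
    :class:`TooManyMissingError` is raised.  Prorated scoring with zero
    missing items coincides with the plain sum.
    """
    if responses.instrument_id != "phq9":
        raise InstrumentError("score_phq9 requires phq9 responses")
    vals = np.asarray(responses.values, dtype=float)
    answered = vals[~np.isnan(vals)]
    n_missing = PHQ9_ITEMS - answered.size
    if n_missing > max_missing:
        raise TooManyMissingError(
            f"{n_missing} missing items exceeds allowance {max_missing}"
        )
    if answered.size == 0:
        raise TooManyMissingError("no answered items")
    total = float(answered.sum() * PHQ9_ITEMS / answered.size)
    return InstrumentScores("phq9", total, None, n_missing)


def score_fertiqol_core(
    responses: ItemResponses,
    min_answered_per_subscale: int = 3,
    reverse_key: Sequence[bool] | None = None,
) -> InstrumentScores:
    """FertiQoL core total and subscale scores, each scaled to 0-100.

    Subscales are the mean of their answered items x 25; the total is the
    mean over all answered core items x 25 (answered-item weighted, so it
    is not in general the average of the subscale scores).  A subscale
    with fewer than ``min_answered_per_subscale`` answered items raises
    :class:`TooManyMissingError`.
    """
    if responses.instrument_id != "fertiqol_core":
        raise InstrumentError("score_fertiqol_core requires fertiqol_core responses")
    vals = np.asarray(responses.values, dtype=float)
    if reverse_key is not None:
        mask = np.asarray(list(reverse_key), dtype=bool)
        if mask.shape != (FERTIQOL_ITEMS,):
            raise InstrumentError("reverse_key must have 24 entries")
        vals = vals.copy()
        vals[mask] = FERTIQOL_RANGE[1] - vals[mask]

    subscales: dict[str, float] = {}
    for name, idx in FERTIQOL_SUBSCALES.items():
        sub = vals[list(idx)]
        answered = sub[~np.isnan(sub)]
        if answered.size < min_answered_per_subscale:
            raise TooManyMissingError(
                f"subscale {name}: only {answered.size} of 6 items answered "
                f"(minimum {min_answered_per_subscale})"
            )
        subscales[name] = float(answered.mean() * 25.0)  # 25 = 100 / 4

    answered_all = vals[~np.isnan(vals)]
    total = float(answered_all.mean() * 25.0)
    n_missing = int(np.isnan(vals).sum())
    return InstrumentScores("fertiqol_core", total, subscales, n_missing)


#: canonical CSV column layout for item-level input
PHQ9_COLUMNS = [f"phq9_{i}" for i in range(1, 10)]
FERTIQOL_COLUMNS = (
    [f"fq_emo_{i}" for i in range(1, 7)]
    + [f"fq_mb_{i}" for i in range(1, 7)]
    + [f"fq_rel_{i}" for i in range(1, 7)]
    + [f"fq_soc_{i}" for i in range(1, 7)]
)


def score_table(
    df: pd.DataFrame,
    max_missing_phq9: int = 0,
    min_answered_per_subscale: int = 3,
    reverse_key: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Score a respondent-per-row item table.

    Expects columns ``phq9_1..phq9_9`` and/or the 24 FertiQoL columns
    ``fq_emo_1..6, fq_mb_1..6, fq_rel_1..6, fq_soc_1..6`` with empty cells
    for missing answers.  Returns one row per respondent with the derived
    scores; any other input columns are carried through unchanged.
    """
    out = df.copy()
    has_phq = all(c in df.columns for c in PHQ9_COLUMNS)
    has_fq = all(c in df.columns for c in FERTIQOL_COLUMNS)
    if not has_phq and not has_fq:
        raise InstrumentError(
            "no complete instrument column set found (phq9_1..9 or fq_*_1..6)"
        )
    if has_phq:
        scores = [
            score_phq9(ItemResponses.phq9(row), max_missing=max_missing_phq9)
            for row in df[PHQ9_COLUMNS].itertuples(index=False)
        ]
        out["phq9_total"] = [s.total for s in scores]
    if has_fq:
        scores = [
            score_fertiqol_core(
                ItemResponses.fertiqol_core(row),
                min_answered_per_subscale=min_answered_per_subscale,
                reverse_key=reverse_key,
            )
            for row in df[FERTIQOL_COLUMNS].itertuples(index=False)
        ]
        out["fertiqol_total"] = [s.total for s in scores]
        for name, key in [
            ("Emotional", "fertiqol_emotional"),
            ("Mind/Body", "fertiqol_mind_body"),
            ("Relational", "fertiqol_relational"),
            ("Social", "fertiqol_social"),
        ]:
            out[key] = [s.subscales[name] for s in scores]
    return out
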