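"""Bundled example summary statistics.

Published summary tables from a cross-sectional study of 180 infertile
couples (Tehran, 2017) in which both members of each couple completed the
PHQ-9 depression questionnaire and the FertiQoL core quality-of-life
instrument.  The study's raw data were never deposited; the printed means,
SDs (rounded to 2 dp) and Pearson correlation matrix (rounded to 2 dp) are
sufficient statistics for every analysis in this package, so they are
shipped as a ready-made :class:`~dyadkit.dyad_data.MomentSummary`.

Variables are named ``<construct>_<role>`` with constructs ``depression``
(PHQ-9 total, 0-27) and the five QoL scores ``qol`` (FertiQoL core total),
``emotional``, ``mind_body``, ``relational``, ``social`` (each 0-100,
higher = better QoL).
"""

from __future__ import annotations

import numpy as np

from .dyad_data import MomentSummary, repair_correlations

__all__ = [
    "STUDY_N",
    "OUTCOMES",
    "VARIABLES",
    "MEANS",
    "SDS",
    "CORRELATIONS",
    "couples_summary",
    "full_summary",
]

STUDY_N = 180

#: QoL outcome constructs, total first
OUTCOMES = ("qol", "emotional", "mind_body", "relational", "social")

#: variable order of the published correlation matrix (all male, then all female)
VARIABLES = [
    "depression_male", "qol_male", "emotional_male",
    "mind_body_male", "relational_male", "social_male",
    "depression_female", "qol_female", "emotional_female",
    "mind_body_female", "relational_female", "social_female",
]

MEANS = np.array([
    4.82, 72.89, 67.34, 74.07, 80.12, 70.05,
    6.76, 67.36, 56.16, 67.31, 77.08, 68.89,
])

SDS = np.array([
    5.47, 15.94, 22.19, 20.00, 16.51, 17.10,
    5.78, 16.11, 22.33, 19.74, 17.33, 18.74,
])

# published lower triangle, one row per variable from the second onward
_LOWER = [
    [-0.61],
    [-0.53, 0.91],
    [-0.59, 0.90, 0.82],
    [-0.34, 0.69, 0.47, 0.46],
    [-0.55, 0.83, 0.67, 0.67, 0.46],
    [0.18, -0.21, -0.17, -0.22, -0.15, -0.17],
    [-0.23, 0.36, 0.36, 0.32, 0.23, 0.28, -0.61],
    [-0.12, 0.25, 0.30, 0.23, 0.08, 0.19, -0.58, 0.89],
    [-0.22, 0.34, 0.33, 0.34, 0.18, 0.27, -0.61, 0.88, 0.80],
    [-0.22, 0.31, 0.27, 0.20, 0.39, 0.19, -0.25, 0.63, 0.36, 0.37],
    [-0.21, 0.30, 0.30, 0.27, 0.15, 0.27, -0.54, 0.86, 0.70, 0.69, 0.44],
]


def _correlation_matrix() -> np.ndarray:
    p = len(VARIABLES)
    R = np.eye(p)
    for i, row in enumerate(_LOWER, start=1):
        for j, r in enumerate(row):
            R[i, j] = R[j, i] = r
    return R


CORRELATIONS = _correlation_matrix()


def couples_summary(outcome: str = "qol") -> MomentSummary:
    """Four-variable summary over (depression_male, depression_female,
    <outcome>_male, <outcome>_female), n = 180 couples.

    The 4x4 blocks of the published matrix are comfortably positive
    definite, so no repair is involved.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    names = [
        "depression_male", "depression_female",
        f"{outcome}_male", f"{outcome}_female",
    ]
    idx = [VARIABLES.index(v) for v in names]
    return MomentSummary(
        variables=names,
        means=MEANS[idx],
        sds=SDS[idx],
        correlations=CORRELATIONS[np.ix_(idx, idx)],
        n=STUDY_N,
    )


def full_summary(repair: bool = False) -> MomentSummary:
    """All 12 variables at once.

    A 12x12 matrix printed to 2 dp can be slightly indefinite; pass
    ``repair=True`` to project it to the nearest correlation matrix
    (eigenvalue clipping) before constructing the summary.
    """
    R = repair_correlations(CORRELATIONS) if repair else CORRELATIONS
    return MomentSummary(
        variables=list(VARIABLES), means=MEANS.copy(), sds=SDS.copy(),
        correlations=R, n=STUDY_N,
    )
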