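"""Primary-variable scores, the PMC index, and consistency grades.

Scoring is equal-weight throughout: the score of primary variable i is the
mean of its binary indicator assignments,

    X_i = sum_j X_ij / T(X_ij),

where T(X_ij) is the number of indicators in primary i, and the index is the
plain sum

    PMC = sum_i X_i,

ranging from 0 to the number of primaries (10 for the default schema).  The
letter grade is the grade-scale band containing the *unrounded* index value;
display rounding (3 decimals, matching the published tables) never feeds back
into banding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import CodingMatrix, PrimaryScoreTable
from .schema import EvaluationSchema, GradeScale

__all__ = ["PolicyScore", "primary_score", "pmc_index", "grade", "score_policies"]


@dataclass(frozen=True)
class PolicyScore:
    """One policy's primary scores, PMC index, and consistency grade."""

    policy_id: str
    primary_ids: tuple[str, ...]
    primary_scores: np.ndarray
    pmc: float
    grade: str

    def score_of(self, primary_id: str) -> float:
        return float(self.primary_scores[self.primary_ids.index(primary_id)])


def primary_score(assignments) -> float:
    """Mean of one primary's binary assignments: (number of ones) / T."""
    arr = np.asarray(assignments)
    if arr.size == 0:
        raise ValueError("a primary must have at least one indicator assignment")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("assignments must be binary (0 or 1)")
    return float(arr.sum() / arr.size)


def pmc_index(primary_scores) -> float:
    """Sum of the per-primary scores; range [0, number of primaries]."""
    arr = np.asarray(primary_scores, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("primary scores must lie in [0, 1]")
    return float(arr.sum())


def grade(pmc: float, scale: GradeScale) -> str:
    """Letter grade of an index value under left-closed/right-open banding."""
    return scale.grade_of(pmc)


def score_policies(
    data: CodingMatrix | PrimaryScoreTable,
    schema: EvaluationSchema,
) -> list[PolicyScore]:
    """Score every policy in a coding matrix or primary-score table.

    From a :class:`CodingMatrix`, each primary's score is the mean of its
    indicator block; from a :class:`PrimaryScoreTable`, the published scores
    are taken at face value.  Policy order is preserved.
    """
    pids = schema.primary_ids
    if isinstance(data, CodingMatrix):
        if tuple(data.indicator_ids) != schema.indicator_ids:
            raise ValueError(
                "coding matrix columns do not match the schema's indicators; "
                "read it with read_coding_matrix(..., schema) first")
        blocks = schema.blocks()
        col = {ind: j for j, ind in enumerate(data.indicator_ids)}
        score_mat = np.column_stack([
            data.values[:, [col[i] for i in blocks[p]]].mean(axis=1)
            for p in pids
        ])
        policy_ids = data.policy_ids
    elif isinstance(data, PrimaryScoreTable):
        if tuple(data.primary_ids) != pids:
            raise ValueError(
                f"primary-score table columns {data.primary_ids} do not match "
                f"the schema's primaries {pids}")
        score_mat = data.scores
        policy_ids = data.policy_ids
    else:
        raise TypeError(
            f"expected CodingMatrix or PrimaryScoreTable, got {type(data).__name__}")

    out = []
    for k, policy in enumerate(policy_ids):
        scores = score_mat[k]
        pmc = pmc_index(scores)
        out.append(PolicyScore(policy, pids, scores, pmc,
                               schema.grade_scale.grade_of(pmc)))
    return out
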