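"""Corpus-level analytics over scored policies.

Per-variable means, the grade distribution, and mean comparisons between two
grade groups (e.g. the good-consistency B group against the acceptable C
group).  Group membership is always recomputed from the grades attached to
the :class:`~pmcindex.scoring.PolicyScore` objects, and all means are
unweighted — each policy counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import PolicyScore

__all__ = ["GradeDistribution", "GroupComparison", "variable_means",
           "grade_distribution", "rank_comparison"]


@dataclass(frozen=True)
class GradeDistribution:
    """Policy counts per grade letter."""

    counts: dict[str, int]
    total: int

    def __getitem__(self, grade: str) -> int:
        return self.counts.get(grade, 0)


@dataclass(frozen=True)
class GroupComparison:
    """Per-variable mean comparison between two grade groups.

    ``table`` rows are X1..Xn plus PMC; columns are the two group means and
    their difference (group1 − group2).
    """

    group1: str
    group2: str
    n1: int
    n2: int
    table: pd.DataFrame


def _frame(scores: list[PolicyScore]) -> pd.DataFrame:
    if not scores:
        raise ValueError("no policy scores given")
    pids = scores[0].primary_ids
    df = pd.DataFrame([s.primary_scores for s in scores],
                      index=[s.policy_id for s in scores], columns=list(pids))
    df["PMC"] = [s.pmc for s in scores]
    return df


def variable_means(scores: list[PolicyScore]) -> pd.Series:
    """Arithmetic mean of each primary score and of PMC across policies."""
    return _frame(scores).mean(axis=0)


def grade_distribution(scores: list[PolicyScore]) -> GradeDistribution:
    """Count policies per grade, ordered as in the schema's grade scale."""
    if not scores:
        raise ValueError("no policy scores given")
    letters = [s.grade for s in scores]
    order = sorted(set(letters))
    counts = {g: letters.count(g) for g in order}
    return GradeDistribution(counts, len(scores))


def rank_comparison(
    scores: list[PolicyScore], g1: str, g2: str
) -> GroupComparison:
    """Per-variable group means and their difference (g1 − g2)."""
    df = _frame(scores)
    grades = np.array([s.grade for s in scores])
    sel1, sel2 = df[grades == g1], df[grades == g2]
    if sel1.empty:
        raise ValueError(f"no policies with grade {g1!r}")
    if sel2.empty:
        raise ValueError(f"no policies with grade {g2!r}")
    m1, m2 = sel1.mean(axis=0), sel2.mean(axis=0)
    table = pd.DataFrame({
        f"mean_{g1}": m1,
        f"mean_{g2}": m2,
        "difference": m1 - m2,
    })
    return GroupComparison(g1, g2, len(sel1), len(sel2), table)
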