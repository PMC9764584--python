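"""Binary coding matrices, primary-score tables, expert scores, and fixtures.

A coding matrix holds the raw 0/1 assignments X_ij: one row per policy, one
column per indicator (every secondary indicator plus the implicit indicator of
each direct-scored primary).  Because published studies typically print only
the per-primary scores X_i, a :class:`PrimaryScoreTable` is an alternative
scoring entry point; the packaged fixture for the 37 Sichuan health promotion
policies is of that form, paired with the expert field-evaluation totals of
the corresponding pilot areas.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import EvaluationSchema

__all__ = [
    "CodingMatrix",
    "PrimaryScoreTable",
    "ExpertScoreVector",
    "CodingError",
    "read_coding_matrix",
    "write_coding_matrix",
    "read_expert_scores",
    "load_sichuan_fixture",
]

_DATA = resources.files("pmcindex") / "data"


class CodingError(ValueError):
    """Raised when a coding sheet or score table fails validation."""


@dataclass(frozen=True)
class CodingMatrix:
    """Policies x indicators binary assignments X_ij.

    values[k, j] is 1 if policy k's text is consistent with indicator j's
    criterion, else 0.
    """

    policy_ids: tuple[str, ...]
    indicator_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_policies, n_indicators), dtype int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.policy_ids), len(self.indicator_ids)):
            raise CodingError(
                f"values shape {vals.shape} does not match "
                f"{len(self.policy_ids)} policies x "
                f"{len(self.indicator_ids)} indicators")
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            raise CodingError(f"non-binary assignment {bad!r}; values must be 0 or 1")
        if len(set(self.policy_ids)) != len(self.policy_ids):
            raise CodingError("duplicate policy ids")
        object.__setattr__(self, "values", vals.astype(np.int64))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.policy_ids),
                            columns=list(self.indicator_ids))


@dataclass(frozen=True)
class PrimaryScoreTable:
    """Per-policy primary-variable scores X_i, each in [0, 1]."""

    policy_ids: tuple[str, ...]
    primary_ids: tuple[str, ...]
    scores: np.ndarray  # shape (n_policies, n_primaries), dtype float

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.policy_ids), len(self.primary_ids)):
            raise CodingError(
                f"scores shape {s.shape} does not match "
                f"{len(self.policy_ids)} policies x "
                f"{len(self.primary_ids)} primaries")
        if ((s < 0) | (s > 1)).any():
            raise CodingError("primary scores must lie in [0, 1]")
        if len(set(self.policy_ids)) != len(self.policy_ids):
            raise CodingError("duplicate policy ids")
        object.__setattr__(self, "scores", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.policy_ids),
                            columns=list(self.primary_ids))


@dataclass(frozen=True)
class ExpertScoreVector:
    """Expert field-evaluation totals, one per pilot area, on a 0-100 scale."""

    area_ids: tuple[str, ...]
    totals: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.totals, dtype=float)
        if t.ndim != 1 or len(t) != len(self.area_ids):
            raise CodingError("one total per area id required")
        if ((t < 0) | (t > 100)).any():
            raise CodingError("expert totals must lie in [0, 100]")
        object.__setattr__(self, "totals", t)


def _validate_columns(cols: list[str], schema: EvaluationSchema) -> None:
    expected = set(schema.indicator_ids)
    got = set(cols)
    missing = sorted(expected - got)
    unknown = sorted(got - expected)
    if missing:
        raise CodingError(f"missing indicator column(s): {missing}")
    if unknown:
        raise CodingError(f"unknown indicator column(s): {unknown}")


def read_coding_matrix(
    source: str | Path | io.TextIOBase,
    schema: EvaluationSchema,
    *,
    blank_as_zero: bool = False,
) -> CodingMatrix:
    """Read a policies x indicators CSV of 0/1 assignments.

    The header row names indicator ids and the first column names policies.
    Columns must match the schema's indicator set exactly (order from the
    schema is imposed on the result).  Non-binary cells are rejected;
    ``blank_as_zero=True`` applies the binary-count convention of scoring an
    absent mention as 0 instead of erroring on empty cells.
    """
    df = pd.read_csv(source, index_col=0, comment="#", dtype=object)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise CodingError(f"duplicate policy id(s): {dupes}")
    _validate_columns([str(c) for c in df.columns], schema)
    df = df[list(schema.indicator_ids)]
    if blank_as_zero:
        df = df.fillna("0")
    raw = df.to_numpy()
    vals = np.zeros(raw.shape, dtype=np.int64)
    for (r, c), cell in np.ndenumerate(raw):
        try:
            num = float(cell)
        except (TypeError, ValueError):
            num = np.nan
        if num not in (0.0, 1.0):
            raise CodingError(
                f"non-binary cell {cell!r} at policy {df.index[r]!r}, "
                f"indicator {df.columns[c]!r}")
        vals[r, c] = int(num)
    return CodingMatrix(tuple(str(i) for i in df.index),
                        tuple(str(c) for c in df.columns), vals)


def write_coding_matrix(matrix: CodingMatrix, path: str | Path) -> None:
    """Write a coding matrix as CSV; inverse of :func:`read_coding_matrix`."""
    matrix.to_frame().rename_axis("policy_id").to_csv(path)


def read_expert_scores(source: str | Path | io.TextIOBase) -> ExpertScoreVector:
    """Read an ``area_id,total`` CSV of expert field-evaluation totals."""
    df = pd.read_csv(source, comment="#")
    if not {"area_id", "total"} <= set(df.columns):
        raise CodingError("expert score CSV needs columns area_id,total")
    return ExpertScoreVector(tuple(str(a) for a in df["area_id"]),
                             df["total"].to_numpy(dtype=float))


def load_sichuan_fixture() -> tuple[PrimaryScoreTable, ExpertScoreVector]:
    """The packaged study data: 37 Sichuan pilot-area health promotion policies.

    Returns the published primary-variable scores (37 policies x X1..X10; the
    indicator-level 0/1 sheet was never released, so scores carry 3-decimal
    rounding) and the expert field-evaluation totals of the 37 pilot areas.
    Pairing is positional: policy Pk was issued by pilot area k.
    """
    with (_DATA / "sichuan_hpp_primary_scores.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0, comment="#")
    table = PrimaryScoreTable(tuple(df.index), tuple(df.columns),
                              df.to_numpy(dtype=float))
    with (_DATA / "sichuan_hpp_expert_scores.csv").open() as fh:
        expert = read_expert_scores(fh)
    return table, expert
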