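"""Variable system driving PMC-Index coding, scoring and grading.

The PMC (Policy Modeling Consistency) index evaluates a policy text against a
hierarchy of evaluation dimensions: *primary variables* (e.g. policy nature,
timeliness, relevance), each owning an ordered list of binary *secondary
indicators* (e.g. "does the text reflect prediction?").  A primary with no
secondaries is *direct-scored*: the policy is coded 0/1 on the primary itself,
which the scoring layer treats as a single implicit indicator so the mean-of-
indicators formula applies uniformly.

The default schema is the 10-primary / 44-secondary system developed for
health promotion policies (HPPs) in China's county/district pilot programme,
together with the four-band consistency grade scale (A excellent, B good,
C acceptable, D poor).  Custom schemas load from YAML via :func:`load_schema`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "SecondaryVariable",
    "PrimaryVariable",
    "GradeBand",
    "GradeScale",
    "EvaluationSchema",
    "SchemaError",
    "default_schema",
    "default_grade_scale",
    "load_schema",
    "dump_schema",
    "validate_schema",
    "emit_multi_input_output_table",
]


class SchemaError(ValueError):
    """Raised when a schema definition is malformed."""


@dataclass(frozen=True)
class SecondaryVariable:
    """A binary yes/no indicator nested within a primary variable.

    The id encodes its parent primary before the colon, e.g. ``"X1:3"``.
    """

    id: str
    label: str
    criterion: str = ""


@dataclass(frozen=True)
class PrimaryVariable:
    """An evaluation dimension owning zero or more secondary indicators."""

    id: str
    label: str
    secondaries: tuple[SecondaryVariable, ...] = ()

    @property
    def direct_scored(self) -> bool:
        """True when the primary is coded 0/1 itself (no secondaries)."""
        return not self.secondaries

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        """Coding-matrix column ids: the secondary ids, or the primary's own
        id when direct-scored (one implicit indicator, T = 1)."""
        if self.direct_scored:
            return (self.id,)
        return tuple(s.id for s in self.secondaries)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_ids)


@dataclass(frozen=True)
class GradeBand:
    """Half-open consistency band ``[lower, upper)`` in index units.

    The band with the greatest upper bound additionally contains its upper
    endpoint, so the scale covers the closed interval up to the maximum
    attainable PMC.
    """

    lower: float
    upper: float
    grade: str
    connotation: str = ""


@dataclass(frozen=True)
class GradeScale:
    """Ordered grade bands partitioning [0, max attainable PMC]."""

    bands: tuple[GradeBand, ...]

    @property
    def max_value(self) -> float:
        return max(b.upper for b in self.bands)

    def grade_of(self, value: float) -> str:
        """Letter grade of an (unrounded) index value.

        Bands are left-closed/right-open; the top band is closed above.
        """
        top = self.max_value
        for band in self.bands:
            if band.lower <= value < band.upper:
                return band.grade
            if value == top == band.upper:
                return band.grade
        raise ValueError(
            f"index value {value!r} outside the grade scale [0, {top}]"
        )


@dataclass(frozen=True)
class EvaluationSchema:
    """Ordered primary variables plus the grade scale used to band the index."""

    name: str
    primaries: tuple[PrimaryVariable, ...]
    grade_scale: GradeScale

    @property
    def primary_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.primaries)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        """All coding-matrix columns, in primary order (implicit ones included)."""
        out: list[str] = []
        for p in self.primaries:
            out.extend(p.indicator_ids)
        return tuple(out)

    @property
    def n_secondaries(self) -> int:
        """Count of explicit secondary indicators (implicit ones excluded)."""
        return sum(len(p.secondaries) for p in self.primaries)

    @property
    def max_pmc(self) -> float:
        """Maximum attainable index: one point per primary."""
        return float(len(self.primaries))

    def blocks(self) -> dict[str, tuple[str, ...]]:
        """Mapping primary id -> its coding-matrix column ids."""
        return {p.id: p.indicator_ids for p in self.primaries}


# --- default HPP schema -----------------------------------------------------

_Y = "Yes is 1, no is 0."

_DEFAULT_PRIMARIES: tuple[tuple[str, str, tuple[tuple[str, str, str], ...]], ...] = (
    ("X1", "Policy nature", (
        ("X1:1", "prediction", f"Does the text reflect prediction? {_Y}"),
        ("X1:2", "supervision", f"Does the text reflect supervision? {_Y}"),
        ("X1:3", "recommendation", f"Does the text reflect suggestion? {_Y}"),
        ("X1:4", "support", f"Does the text reflect support? {_Y}"),
        ("X1:5", "guidance", f"Does the text reflect guidance? {_Y}"),
        ("X1:6", "diagnosis", f"Does the text reflect diagnosis? {_Y}"),
        ("X1:7", "description", f"Does the text reflect description? {_Y}"),
    )),
    ("X2", "Policy timeliness", (
        ("X2:1", "long term", f"Does it involve content longer than 5 years? {_Y}"),
        ("X2:2", "medium term", f"Does it involve a 3-5 year horizon? {_Y}"),
        ("X2:3", "short term", f"Does it involve a 1-3 year horizon? {_Y}"),
        ("X2:4", "temporary", f"Does it involve content under 1 year? {_Y}"),
    )),
    ("X3", "Policy relevance", (
        ("X3:1", "national policy", f"Is it related to national policies? {_Y}"),
        ("X3:2", "provincial policy", f"Is it related to provincial policies? {_Y}"),
        ("X3:3", "municipal policy", f"Is it related to municipal policies? {_Y}"),
        ("X3:4", "other policies", f"Is it related to other (e.g. county) policies? {_Y}"),
    )),
    ("X4", "Incentives and constraints", (
        ("X4:1", "talent incentives", f"Is there talent-incentive content? {_Y}"),
        ("X4:2", "fiscal incentives", f"Are there fiscal or tax incentives? {_Y}"),
        ("X4:3", "administrative approval incentives",
         f"Is there administrative approval support? {_Y}"),
        ("X4:4", "laws and regulations", f"Do laws and regulations support it? {_Y}"),
    )),
    ("X5", "Policy subjects", (
        ("X5:1", "politics", f"Does the policy involve the political field? {_Y}"),
        ("X5:2", "economy", f"Does the policy involve the economic field? {_Y}"),
        ("X5:3", "technology", f"Does the policy involve the technical field? {_Y}"),
        ("X5:4", "society", f"Does the policy involve social welfare and livelihood? {_Y}"),
        ("X5:5", "environmental protection",
         f"Does the policy involve environmental protection? {_Y}"),
    )),
    ("X6", "Policy content", (
        ("X6:1", "improve the policy system",
         f"Is the content to improve the policy system? {_Y}"),
        ("X6:2", "strengthen organizational management",
         f"Is the content to strengthen organizational management? {_Y}"),
        ("X6:3", "building a healthy place",
         f"Is the content to establish a healthy place? {_Y}"),
        ("X6:4", "spreading health culture",
         f"Is the content to spread a healthy culture? {_Y}"),
        ("X6:5", "creating a healthy environment",
         f"Is the content to create a healthy environment? {_Y}"),
        ("X6:6", "foster healthy people",
         f"Is the content to cultivate healthy people? {_Y}"),
    )),
    ("X7", "Policy evaluation", (
        ("X7:1", "specific goals", f"Does the policy have specific goals? {_Y}"),
        ("X7:2", "detailed planning", f"Is the policy planning detailed? {_Y}"),
        ("X7:3", "scientific programme", f"Is the policy programme scientific? {_Y}"),
        ("X7:4", "sufficient basis", f"Is the policy basis sufficient? {_Y}"),
        ("X7:5", "clear rights and responsibilities",
         f"Does the policy have clear rights and responsibilities? {_Y}"),
    )),
    ("X8", "Issuing agency", (
        ("X8:1", "people's congress",
         f"Is the issuing agency the people's congress? {_Y}"),
        ("X8:2", "party commission",
         f"Is the issuing agency the party commission? {_Y}"),
        ("X8:3", "government offices",
         f"Is the issuing agency the local government office? {_Y}"),
        ("X8:4", "other government departments",
         f"Is the issuing agency another functional department? {_Y}"),
    )),
    ("X9", "Policy objects", (
        ("X9:1", "public institutions",
         f"Does it affect institutions (schools, hospitals, ...)? {_Y}"),
        ("X9:2", "enterprise units", f"Does it affect enterprise units? {_Y}"),
        ("X9:3", "public environment",
         f"Does it affect the public environment (parks, trails, ...)? {_Y}"),
        ("X9:4", "communities", f"Does it affect the community? {_Y}"),
        ("X9:5", "families and individuals",
         f"Does it affect families and individuals? {_Y}"),
    )),
    ("X10", "Policy disclosure", ()),
)

_DEFAULT_BANDS = (
    (9.0, 10.0, "A", "Excellent consistency"),
    (7.0, 9.0, "B", "Good consistency"),
    (5.0, 7.0, "C", "Acceptable consistency"),
    (0.0, 5.0, "D", "Poor consistency"),
)


def default_grade_scale() -> GradeScale:
    """The four-band A/B/C/D consistency scale on [0, 10]."""
    return GradeScale(tuple(GradeBand(*b) for b in _DEFAULT_BANDS))


def default_schema() -> EvaluationSchema:
    """The packaged HPP evaluation system: 10 primaries, 44 secondaries.

    X10 (policy disclosure) has no secondaries and is direct-scored.
    """
    primaries = tuple(
        PrimaryVariable(pid, label,
                        tuple(SecondaryVariable(*s) for s in secs))
        for pid, label, secs in _DEFAULT_PRIMARIES
    )
    return EvaluationSchema("hpp-default", primaries, default_grade_scale())


# --- config I/O -------------------------------------------------------------

def load_schema(config_source: str | io.TextIOBase) -> EvaluationSchema:
    """Load a schema from YAML text (or an open text stream).

    Expected keys: ``name``, ``primaries`` (list of ``{id, label,
    secondaries: [{id, label, criterion}]}``) and ``grade_bands`` (list of
    ``{min, max, grade, connotation}``).  The loaded schema is validated and a
    :class:`SchemaError` raised on any violation.
    """
    text = config_source.read() if hasattr(config_source, "read") else config_source
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"schema config does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("schema config must be a mapping")
    try:
        primaries = tuple(
            PrimaryVariable(
                str(p["id"]), str(p.get("label", p["id"])),
                tuple(
                    SecondaryVariable(str(s["id"]), str(s.get("label", s["id"])),
                                      str(s.get("criterion", "")))
                    for s in (p.get("secondaries") or ())
                ),
            )
            for p in doc.get("primaries", ())
        )
        bands = tuple(
            GradeBand(float(b["min"]), float(b["max"]), str(b["grade"]),
                      str(b.get("connotation", "")))
            for b in doc.get("grade_bands", ())
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed schema config: {exc}") from exc
    schema = EvaluationSchema(str(doc.get("name", "unnamed")), primaries,
                              GradeScale(bands))
    violations = validate_schema(schema)
    if violations:
        raise SchemaError("; ".join(violations))
    return schema


def dump_schema(schema: EvaluationSchema) -> str:
    """Serialise a schema to YAML; inverse of :func:`load_schema`."""
    doc = {
        "name": schema.name,
        "primaries": [
            {
                "id": p.id,
                "label": p.label,
                "secondaries": [
                    {"id": s.id, "label": s.label, "criterion": s.criterion}
                    for s in p.secondaries
                ],
            }
            for p in schema.primaries
        ],
        "grade_bands": [
            {"min": b.lower, "max": b.upper, "grade": b.grade,
             "connotation": b.connotation}
            for b in schema.grade_scale.bands
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# --- validation -------------------------------------------------------------

def validate_schema(schema: EvaluationSchema) -> list[str]:
    """Report every violated invariant; an empty list means well-formed.

    Checks: unique primary ids, unique secondary ids, each secondary id
    prefixed by its parent primary id (before the colon), and grade bands that
    partition [0, number of primaries] without gap or overlap.
    """
    violations: list[str] = []
    pids = [p.id for p in schema.primaries]
    if len(set(pids)) != len(pids):
        dupes = sorted({i for i in pids if pids.count(i) > 1})
        violations.append(f"duplicate primary ids: {dupes}")
    sids = [s.id for p in schema.primaries for s in p.secondaries]
    if len(set(sids)) != len(sids):
        dupes = sorted({i for i in sids if sids.count(i) > 1})
        violations.append(f"duplicate secondary ids: {dupes}")
    for p in schema.primaries:
        for s in p.secondaries:
            if s.id.split(":", 1)[0] != p.id:
                violations.append(
                    f"secondary {s.id!r} does not encode its parent {p.id!r}")

    bands = sorted(schema.grade_scale.bands, key=lambda b: b.lower)
    if not bands:
        violations.append("grade scale has no bands")
        return violations
    for b in bands:
        if b.lower >= b.upper:
            violations.append(f"empty or inverted band {b.grade!r}: "
                              f"[{b.lower}, {b.upper})")
    if bands[0].lower != 0:
        violations.append(f"grade bands start at {bands[0].lower}, not 0")
    for lo, hi in zip(bands, bands[1:]):
        if lo.upper > hi.lower:
            violations.append(f"bands {lo.grade!r} and {hi.grade!r} overlap")
        elif lo.upper < hi.lower:
            violations.append(f"gap between bands {lo.grade!r} and {hi.grade!r}")
    if schema.primaries and bands[-1].upper != schema.max_pmc:
        violations.append(
            f"grade bands cover [0, {bands[-1].upper}] but the maximum "
            f"attainable index is {schema.max_pmc}")
    return violations


# --- multi-input-output table ----------------------------------------------

def emit_multi_input_output_table(schema: EvaluationSchema) -> pd.DataFrame:
    """Columnar layout: one column per primary, rows are its secondary ids.

    Direct-scored primaries render a single ``"-"`` cell; shorter columns are
    padded with empty strings.  This is the standard multi-input-output table
    used to organise the coding sheet.
    """
    violations = validate_schema(schema)
    if violations:
        raise SchemaError("; ".join(violations))
    cols = {
        p.id: (["-"] if p.direct_scored else [s.id for s in p.secondaries])
        for p in schema.primaries
    }
    depth = max((len(v) for v in cols.values()), default=0)
    data = {pid: ids + [""] * (depth - len(ids)) for pid, ids in cols.items()}
    return pd.DataFrame(data, columns=list(cols), dtype=object)
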