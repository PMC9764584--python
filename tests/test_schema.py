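"""Variable-system definition, validation, config round-trip, and the
multi-input-output table layout."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmcindex as pmc


class TestDefaultSchema:
    def test_structure(self, schema):
        assert len(schema.primaries) == 10
        assert schema.n_secondaries == 44
        assert [len(p.secondaries) for p in schema.primaries] == \
            [7, 4, 4, 4, 5, 6, 5, 4, 5, 0]

    def test_direct_scored_disclosure(self, schema):
        x10 = schema.primaries[-1]
        assert x10.id == "X10" and x10.direct_scored
        # implicit single indicator so the mean formula applies with T = 1
        assert x10.indicator_ids == ("X10",) and x10.n_indicators == 1
        assert len(schema.indicator_ids) == 45

    def test_default_is_well_formed(self, schema):
        assert pmc.validate_schema(schema) == []

    @pytest.mark.parametrize("value,expected", [
        (9.0, "A"), (10.0, "A"),         # top band closed above
        (7.0, "B"), (8.99, "B"),         # left-closed boundary
        (5.0, "C"), (6.99, "C"),
        (0.0, "D"), (4.999, "D"),
    ])
    def test_grade_bands(self, schema, value, expected):
        assert schema.grade_scale.grade_of(value) == expected

    def test_grade_outside_scale_rejected(self, schema):
        with pytest.raises(ValueError):
            schema.grade_scale.grade_of(10.5)

    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_every_index_value_has_exactly_one_band(self, value):
        scale = pmc.default_grade_scale()
        hits = [b.grade for b in scale.bands
                if b.lower <= value < b.upper or (value == 10 and b.upper == 10)]
        assert len(hits) == 1


class TestConfigIO:
    def test_round_trip_identity(self, schema):
        again = pmc.load_schema(pmc.dump_schema(schema))
        assert again == schema

    def test_small_schema_by_construction(self):
        cfg = """
name: mini
primaries:
  - id: X1
    label: one
    secondaries:
      - {id: "X1:1", label: a}
      - {id: "X1:2", label: b}
  - id: X2
    label: two
    secondaries:
      - {id: "X2:1", label: c}
      - {id: "X2:2", label: d}
grade_bands:
  - {min: 1, max: 2, grade: A}
  - {min: 0, max: 1, grade: B}
"""
        schema = pmc.load_schema(cfg)
        assert schema.n_secondaries == 4
        assert schema.primary_ids == ("X1", "X2")

    def test_duplicate_secondary_id_rejected(self):
        cfg = """
name: dup
primaries:
  - id: X1
    secondaries: [{id: "X1:1"}, {id: "X1:1"}]
grade_bands: [{min: 0, max: 1, grade: A}]
"""
        with pytest.raises(pmc.SchemaError, match="duplicate"):
            pmc.load_schema(cfg)

    def test_parse_failure(self):
        with pytest.raises(pmc.SchemaError, match="parse|mapping"):
            pmc.load_schema(": not [valid yaml")


class TestValidation:
    def test_overlapping_bands_reported(self, tiny_schema):
        bad = pmc.EvaluationSchema(
            tiny_schema.name, tiny_schema.primaries,
            pmc.GradeScale((pmc.GradeBand(0.0, 1.2, "B"),
                            pmc.GradeBand(1.0, 2.0, "A"))))
        report = pmc.validate_schema(bad)
        assert len(report) == 1 and "overlap" in report[0]

    def test_band_coverage_vs_max_index(self, schema):
        short = pmc.EvaluationSchema(
            "short", schema.primaries,
            pmc.GradeScale((pmc.GradeBand(0.0, 5.0, "D"),
                            pmc.GradeBand(5.0, 8.0, "C"))))
        report = pmc.validate_schema(short)
        assert any("maximum attainable" in v for v in report)

    def test_orphan_secondary_prefix(self):
        schema = pmc.EvaluationSchema(
            "orphan",
            (pmc.PrimaryVariable("X1", "one",
                                 (pmc.SecondaryVariable("X9:1", "stray"),)),),
            pmc.GradeScale((pmc.GradeBand(0.0, 1.0, "A"),)))
        report = pmc.validate_schema(schema)
        assert any("parent" in v for v in report)


class TestMultiInputOutputTable:
    def test_default_layout(self, schema):
        table = pmc.emit_multi_input_output_table(schema)
        assert list(table.columns) == [f"X{i}" for i in range(1, 11)]
        assert list(table["X1"]) == [f"X1:{j}" for j in range(1, 8)]
        # direct-scored primary renders a single "-" cell, padded below
        assert table["X10"][0] == "-"
        assert all(v == "" for v in table["X10"][1:])

    def test_single_primary(self):
        schema = pmc.EvaluationSchema(
            "solo",
            (pmc.PrimaryVariable("X1", "one", tuple(
                pmc.SecondaryVariable(f"X1:{j}", str(j)) for j in (1, 2, 3))),),
            pmc.GradeScale((pmc.GradeBand(0.0, 1.0, "A"),)))
        table = pmc.emit_multi_input_output_table(schema)
        assert table.shape == (3, 1)
        assert list(table["X1"]) == ["X1:1", "X1:2", "X1:3"]

    def test_invalid_schema_rejected(self, tiny_schema):
        bad = pmc.EvaluationSchema(
            "bad", tiny_schema.primaries,
            pmc.GradeScale((pmc.GradeBand(0.5, 2.0, "A"),)))
        with pytest.raises(pmc.SchemaError):
            pmc.emit_multi_input_output_table(bad)
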