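"""Equal-weight scoring: per-primary means, the summed index, grading, and
oracle equivalence against brute-force counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmcindex as pmc
from conftest import brute_force_scores


class TestPrimaryScore:
    @pytest.mark.parametrize("assignments,expected", [
        ([1, 1, 1, 1, 1, 1, 0], 6 / 7),   # prints as 0.857
        ([0, 0, 0, 0], 0.0),
        ([1, 1, 1, 1, 1], 1.0),
    ])
    def test_mean_of_block(self, assignments, expected):
        assert pmc.primary_score(assignments) == pytest.approx(expected)

    def test_empty_and_non_binary_rejected(self):
        with pytest.raises(ValueError):
            pmc.primary_score([])
        with pytest.raises(ValueError):
            pmc.primary_score([0, 2])


class TestPmcIndex:
    @pytest.mark.parametrize("scores,expected", [
        # published per-primary rows and their printed index values
        ((1.0, 1.0, 1.0, 0.75, 1.0, 1.0, 1.0, 0.25, 1.0, 1.0), 9.000),
        ((0.857, 0.5, 0.5, 0.25, 0.8, 1.0, 1.0, 0.25, 1.0, 1.0), 7.157),
        (np.zeros(10), 0.0),
    ])
    def test_sum(self, scores, expected):
        assert pmc.pmc_index(scores) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pmc.pmc_index([0.5, 1.1])


class TestGrade:
    @pytest.mark.parametrize("value,expected", [
        (9.000, "A"), (6.198, "C"), (4.021, "D"),
        (7.000, "B"),  # boundary: left-closed
    ])
    def test_banding(self, schema, value, expected):
        assert pmc.grade(value, schema.grade_scale) == expected


class TestScorePolicies:
    def test_all_ones_matrix(self, schema):
        m = pmc.CodingMatrix(("P1", "P2"), schema.indicator_ids,
                             np.ones((2, 45), dtype=int))
        for s in pmc.score_policies(m, schema):
            assert s.pmc == pytest.approx(10.0)
            assert s.grade == "A"

    def test_one_hit_per_block_sums_unit_fractions(self, schema):
        row = np.zeros(45, dtype=int)
        pos = 0
        for prim in schema.primaries:
            row[pos] = 1
            pos += prim.n_indicators
        m = pmc.CodingMatrix(("P1",), schema.indicator_ids, row[None, :])
        (score,) = pmc.score_policies(m, schema)
        expected = sum(1 / p.n_indicators for p in schema.primaries)
        assert expected == pytest.approx(2.909524, abs=1e-6)
        assert score.pmc == pytest.approx(expected)

    def test_fixture_published_index(self, cohort_scores):
        by_id = {s.policy_id: s for s in cohort_scores}
        assert len(cohort_scores) == 37
        assert by_id["P12"].pmc == pytest.approx(8.514, abs=0.002)

    def test_wrong_columns_rejected(self, schema):
        table = pmc.PrimaryScoreTable(("P1",), ("X1", "X2"),
                                      np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="do not match"):
            pmc.score_policies(table, schema)

    def test_wrong_input_type(self, schema):
        with pytest.raises(TypeError):
            pmc.score_policies(np.ones((2, 45)), schema)


@st.composite
def coding_rows(draw, n_indicators):
    n = draw(st.integers(min_value=1, max_value=4))
    return [draw(st.lists(st.integers(0, 1), min_size=n_indicators,
                          max_size=n_indicators)) for _ in range(n)]


class TestProperties:
    @given(st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_oracle_equivalence(self, data):
        """Vectorised scoring agrees with an explicit count-and-divide loop."""
        schema = pmc.default_schema()
        rows = data.draw(coding_rows(len(schema.indicator_ids)))
        m = pmc.CodingMatrix(tuple(f"P{i}" for i in range(len(rows))),
                             schema.indicator_ids, np.array(rows))
        scored = pmc.score_policies(m, schema)
        expected = brute_force_scores(rows, schema)
        for s, (exp_scores, exp_pmc) in zip(scored, expected):
            np.testing.assert_allclose(s.primary_scores, exp_scores, atol=1e-12)
            assert s.pmc == pytest.approx(exp_pmc, abs=1e-9)
            assert 0.0 <= s.pmc <= schema.max_pmc

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_single_flip(self, data):
        """Flipping one 0 to 1 raises the index by exactly 1/T of its block."""
        schema = pmc.default_schema()
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        row = rng.integers(0, 2, size=45)
        zeros = np.flatnonzero(row == 0)
        if zeros.size == 0:
            return
        j = int(zeros[data.draw(st.integers(0, zeros.size - 1))])
        flipped = row.copy()
        flipped[j] = 1
        before, after = (
            pmc.score_policies(
                pmc.CodingMatrix(("P1",), schema.indicator_ids, r[None, :]),
                schema)[0].pmc
            for r in (row, flipped))
        pos = 0
        for prim in schema.primaries:
            if pos <= j < pos + prim.n_indicators:
                t = prim.n_indicators
                break
            pos += prim.n_indicators
        assert after - before == pytest.approx(1 / t, abs=1e-9)
        assert after >= before
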