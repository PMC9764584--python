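import numpy as np
import pytest

import pmcindex as pmc


@pytest.fixture(scope="session")
def schema():
    return pmc.default_schema()


@pytest.fixture(scope="session")
def sichuan():
    """Packaged cohort: (primary-score table, expert totals)."""
    return pmc.load_sichuan_fixture()


@pytest.fixture(scope="session")
def cohort_scores(schema, sichuan):
    table, _ = sichuan
    return pmc.score_policies(table, schema)


@pytest.fixture()
def tiny_schema():
    """Two primaries (2 and 3 secondaries) with a proportional grade scale."""
    return pmc.EvaluationSchema(
        "tiny",
        (
            pmc.PrimaryVariable("X1", "first", (
                pmc.SecondaryVariable("X1:1", "a"),
                pmc.SecondaryVariable("X1:2", "b"),
            )),
            pmc.PrimaryVariable("X2", "second", (
                pmc.SecondaryVariable("X2:1", "c"),
                pmc.SecondaryVariable("X2:2", "d"),
                pmc.SecondaryVariable("X2:3", "e"),
            )),
        ),
        pmc.GradeScale((
            pmc.GradeBand(1.5, 2.0, "A"),
            pmc.GradeBand(1.0, 1.5, "B"),
            pmc.GradeBand(0.0, 1.0, "C"),
        )),
    )


def brute_force_scores(values, schema):
    """Independent oracle: per-primary mean and index via explicit loops."""
    out = []
    for row in values:
        scores, pos = [], 0
        for prim in schema.primaries:
            t = prim.n_indicators
            ones = 0
            for j in range(pos, pos + t):
                if row[j] == 1:
                    ones += 1
            scores.append(ones / t)
            pos += t
        out.append((scores, sum(scores)))
    return out


def pmc_of(scores):
    return np.array([s.pmc for s in scores])
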