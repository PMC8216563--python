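"""Shared fixtures and hypothesis strategies for the test suite."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from olyscore import (
    MISSING,
    CriterionScore,
    EstuaryRecord,
    default_criteria,
    default_index_definitions,
    generate_paperlike_fixture,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

KEY_TO_ID = {c.key: c.id for c in default_criteria()}


def make_record(name="Test Estuary", region="WA", default=None, **by_key) -> EstuaryRecord:
    """Build a record from criterion keys; unlisted criteria get `default`.

    ``default=None`` leaves unlisted criteria absent from the mapping (which
    scores identically to MISSING); pass an int or MISSING to fill them.
    """
    scores = {}
    if default is not None:
        scores = {cid: CriterionScore(default) for cid in KEY_TO_ID.values()}
    for key, value in by_key.items():
        scores[KEY_TO_ID[key]] = value if isinstance(value, CriterionScore) else CriterionScore(value)
    return EstuaryRecord(name=name, region=region, scores=scores)


def oracle_index(record: EstuaryRecord, definition) -> Fraction:
    """Independent brute-force index: explicit loop over all 14 criteria,
    pure Fraction arithmetic, veto checked inline."""
    total = Fraction(0)
    maximum = Fraction(0)
    vetoed = False
    for criterion in default_criteria():
        if criterion.id not in definition.weights:
            continue
        weight = definition.weights[criterion.id]
        score = record.scores.get(criterion.id)
        value = 0 if score is None or score.is_missing else int(score.value)
        total += Fraction(weight) * value
        maximum += Fraction(weight) * 2
        if criterion.id in definition.override_criteria and value == 0:
            vetoed = True
    return Fraction(0) if vetoed else total / maximum


# --- hypothesis strategies ---------------------------------------------------

score_values = st.one_of(st.sampled_from([0, 1, 2]), st.just(MISSING))
certainties = st.one_of(st.none(), st.sampled_from([1, 2, 3]))


@st.composite
def criterion_scores(draw):
    return CriterionScore(value=draw(score_values), certainty=draw(certainties))


@st.composite
def estuary_records(draw, name="H"):
    scores = {cid: draw(criterion_scores()) for cid in KEY_TO_ID.values()}
    region = draw(st.sampled_from(["BCC", "WA", "OR", "CA", "BCM"]))
    return EstuaryRecord(name=name, region=region, scores=scores)


# --- fixtures ----------------------------------------------------------------

@pytest.fixture(scope="session")
def definitions():
    return default_index_definitions()


@pytest.fixture(scope="session")
def criteria():
    return default_criteria()


@pytest.fixture(scope="session")
def paperlike():
    return generate_paperlike_fixture(seed=0)
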