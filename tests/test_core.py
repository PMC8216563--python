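"""Core scoring arithmetic: defaults, weighted sums, vetoes, classification."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from olyscore import (
    MISSING,
    ConfigurationError,
    CriterionScore,
    IndexDefinition,
    ScoreValidationError,
    classify_priority,
    default_criteria,
    default_index_definitions,
    normalized_index,
    override_triggered,
    weighted_raw_score,
)

from .conftest import estuary_records, make_record, oracle_index


class TestDefaults:
    def test_registry_has_fourteen_criteria_in_order(self):
        criteria = default_criteria()
        assert len(criteria) == 14
        assert [c.id for c in criteria] == list(range(1, 15))

    def test_registry_keys(self):
        keys = [c.key for c in default_criteria()]
        assert keys == [
            "recruitment", "extinction_risk", "mortality", "isolation",
            "hatchery", "safe_to_eat", "harvest_regulations", "growth",
            "bivalves_farmed", "management_plan", "community_oyster_restoration",
            "community_bivalve_restoration", "tribes_first_nations",
            "community_grow_harvest",
        ]

    def test_recruitment_criterion_content(self):
        first = default_criteria()[0]
        assert first.key == "recruitment"
        assert "recruitment" in first.rationale.lower()

    @pytest.mark.parametrize(
        "name,weights,override,max_raw",
        [
            ("ecological_priority", {1: 4, 2: 3, 3: 2, 4: 2}, set(), 22),
            ("community_restoration", {3: 2, 5: 1, 10: 2, 11: 2, 12: 1, 13: 1}, set(), 18),
            ("community_harvest",
             {3: 2, 5: 1, 6: 3, 7: 2, 8: 1, 9: 1, 13: 1, 14: 1}, {6, 7}, 24),
            ("commercial_production",
             {3: 1, 5: 2, 6: 3, 8: 1, 9: 1, 14: 1}, {6}, 18),
        ],
    )
    def test_default_definitions(self, definitions, name, weights, override, max_raw):
        d = definitions[name]
        assert dict(d.weights) == weights
        assert set(d.override_criteria) == override
        assert d.max_raw == max_raw
        assert d.threshold == Fraction(1, 2)


class TestScoreTypes:
    @pytest.mark.parametrize("bad", [3, -1, 1.5, "2"])
    def test_score_scale_enforced(self, bad):
        with pytest.raises(ScoreValidationError):
            CriterionScore(bad)

    def test_missing_distinct_from_zero(self):
        assert CriterionScore(MISSING) != CriterionScore(0)
        assert CriterionScore(MISSING).is_missing
        assert CriterionScore(MISSING).effective == 0

    @pytest.mark.parametrize("bad", [0, 4, "**"])
    def test_certainty_scale_enforced(self, bad):
        with pytest.raises(ScoreValidationError):
            CriterionScore(1, certainty=bad)

    @pytest.mark.parametrize("weights", [{1: 0}, {1: -2}, {1: 1.5}, {}])
    def test_invalid_weights_rejected(self, weights):
        with pytest.raises(ConfigurationError):
            IndexDefinition("x", weights)

    def test_override_must_be_weighted(self):
        with pytest.raises(ConfigurationError):
            IndexDefinition("x", {1: 1}, override_criteria=frozenset({6}))


class TestWeightedRawScore:
    def test_all_zero_record(self, definitions):
        record = make_record(default=0)
        assert weighted_raw_score(record, definitions["ecological_priority"]) == 0

    def test_hand_summed_example(self, definitions):
        record = make_record(recruitment=2, extinction_risk=2, mortality=1, isolation=0)
        assert weighted_raw_score(record, definitions["ecological_priority"]) == 16

    def test_missing_contributes_zero(self, definitions):
        record = make_record(recruitment=2, extinction_risk=MISSING,
                             mortality=2, isolation=2)
        assert weighted_raw_score(record, definitions["ecological_priority"]) == 16

    def test_unknown_criterion_id_rejected(self):
        bad = IndexDefinition("bad", {99: 1})
        with pytest.raises(ConfigurationError):
            weighted_raw_score(make_record(default=1), bad)


class TestOverride:
    def test_safe_to_eat_zero_triggers_harvest_veto(self, definitions):
        record = make_record(default=2, safe_to_eat=0)
        assert override_triggered(record, definitions["community_harvest"])

    def test_empty_override_set_never_triggers(self, definitions):
        record = make_record(default=0)
        assert not override_triggered(record, definitions["ecological_priority"])

    def test_missing_override_criterion_triggers(self, definitions):
        record = make_record(default=2, safe_to_eat=MISSING)
        assert override_triggered(record, definitions["commercial_production"])


class TestNormalizedIndex:
    def test_all_high_ecological_record_scores_one(self, definitions):
        record = make_record(recruitment=2, extinction_risk=2, mortality=2, isolation=2)
        assert normalized_index(record, definitions["ecological_priority"]) == 1

    def test_exact_half(self, definitions):
        record = make_record(recruitment=2, extinction_risk=1, mortality=0, isolation=0)
        assert normalized_index(record, definitions["ecological_priority"]) == Fraction(1, 2)

    def test_commercial_third(self, definitions):
        record = make_record(default=0, safe_to_eat=2)
        score = normalized_index(record, definitions["commercial_production"])
        assert score == Fraction(6, 18) == Fraction(1, 3)

    def test_veto_forces_zero(self, definitions):
        record = make_record(default=2, safe_to_eat=0)
        assert normalized_index(record, definitions["community_harvest"]) == 0


class TestClassifyPriority:
    @pytest.mark.parametrize(
        "score,threshold,expected",
        [
            (0.5, 0.5, True),
            (Fraction(11, 22), Fraction(1, 2), True),
            (Fraction(10, 22), Fraction(1, 2), False),
            (Fraction(1), Fraction(1), True),
        ],
    )
    def test_boundary_exact(self, score, threshold, expected):
        assert classify_priority(score, threshold) is expected

    def test_float_threshold_read_as_decimal(self):
        # 0.7 means 7/10 exactly, not the nearest binary float
        assert classify_priority(Fraction(7, 10), 0.7)


# --- properties ---------------------------------------------------------------

@given(record=estuary_records())
def test_scores_lie_in_unit_interval(record, definitions):
    for d in definitions.values():
        assert 0 <= normalized_index(record, d) <= 1


@given(record=estuary_records())
def test_score_one_iff_all_weighted_criteria_high(record, definitions):
    for d in definitions.values():
        full = all(record.scores[cid].effective == 2 for cid in d.weights)
        assert (normalized_index(record, d) == 1) == (full and not override_triggered(record, d))


@given(record=estuary_records(), cid=st.integers(1, 14))
def test_monotone_in_every_criterion(record, cid, definitions):
    """Raising one criterion (MISSING->any, 0->1, 1->2) never lowers any index."""
    current = record.scores[cid]
    upgrades = [0, 1, 2] if current.is_missing else list(range(int(current.value) + 1, 3))
    for new_value in upgrades:
        improved = record.scores | {cid: CriterionScore(new_value)}
        better = type(record)(record.name, record.region, improved)
        for d in definitions.values():
            assert normalized_index(better, d) >= normalized_index(record, d)


@given(record=estuary_records())
def test_missing_equivalent_to_zero_for_scoring(record, definitions):
    filled = {
        cid: CriterionScore(0) if s.is_missing else s
        for cid, s in record.scores.items()
    }
    zeroed = type(record)(record.name, record.region, filled)
    for d in definitions.values():
        assert normalized_index(record, d) == normalized_index(zeroed, d)


@given(record=estuary_records(), factor=st.integers(1, 7))
def test_weight_scale_invariance(record, factor, definitions):
    for d in definitions.values():
        scaled = IndexDefinition(d.name, {c: w * factor for c, w in d.weights.items()},
                                 d.override_criteria, d.threshold)
        assert normalized_index(record, scaled) == normalized_index(record, d)


@given(record=estuary_records())
def test_matches_bruteforce_oracle(record, definitions):
    for d in definitions.values():
        assert normalized_index(record, d) == oracle_index(record, d)
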