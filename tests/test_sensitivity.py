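"""Priority-set stability: perturbation schemes, Jaccard statistics, seeds."""

import math

import numpy as np
import pytest

from olyscore import (
    ConfigurationError,
    CriterionScore,
    GeneratorConfig,
    PerturbationScheme,
    compare_priority_sets,
    default_index_definitions,
    generate_table,
    run_sensitivity,
)

from .conftest import make_record


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A", "B"}, {"C"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            (set(), set(), 1.0),
            (set(), {"A"}, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert compare_priority_sets(a, b) == expected


@pytest.fixture(scope="module")
def small_table():
    return generate_table(GeneratorConfig(
        n_estuaries=8, core_all_missing_rate=0.0,
        missing_rate_by_region={r: 0.0 for r in ("BCC", "WA", "OR", "CA", "BCM")},
        seed=11))


class TestScheme:
    def test_zero_draws_rejected(self):
        with pytest.raises(ConfigurationError):
            PerturbationScheme(n_draws=0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            PerturbationScheme(kind="shuffle")

    def test_probability_range_enforced(self):
        with pytest.raises(ConfigurationError):
            PerturbationScheme(flip_probabilities={1: 1.5})


class TestNoNoiseIdentity:
    def test_zero_flip_probabilities_reproduce_baseline(self, small_table):
        scheme = PerturbationScheme(
            kind="score_resample", n_draws=25, seed=4,
            flip_probabilities={1: 0.0, 2: 0.0, 3: 0.0, None: 0.0})
        report = run_sensitivity(small_table, scheme=scheme)
        for index, freqs in report.priority_frequency.items():
            baseline = set(report.baseline_priority[index])
            for name, freq in freqs.items():
                assert freq == (1.0 if name in baseline else 0.0)
        assert all(j == 1.0 for j in report.jaccard_mean.values())

    def test_zero_weight_jitter_reproduces_baseline(self, small_table):
        scheme = PerturbationScheme(kind="weight_jitter", n_draws=10, seed=4,
                                    weight_jitter_range=0)
        report = run_sensitivity(small_table, scheme=scheme)
        assert all(j == 1.0 for j in report.jaccard_mean.values())


class TestSeedDeterminism:
    @pytest.mark.parametrize("kind", ["score_resample", "weight_jitter"])
    def test_same_seed_same_report(self, small_table, kind):
        scheme = PerturbationScheme(kind=kind, n_draws=40, seed=123)
        a = run_sensitivity(small_table, scheme=scheme)
        b = run_sensitivity(small_table, scheme=scheme)
        assert a.to_dict() == b.to_dict()

    def test_different_seeds_usually_differ(self, small_table):
        a = run_sensitivity(small_table,
                            scheme=PerturbationScheme(n_draws=40, seed=1))
        b = run_sensitivity(small_table,
                            scheme=PerturbationScheme(n_draws=40, seed=2))
        assert a.to_dict() != b.to_dict()


class TestLeaveOneOut:
    def test_one_rerun_per_weighted_criterion(self, small_table):
        eco = {"ecological_priority": default_index_definitions()["ecological_priority"]}
        scheme = PerturbationScheme(kind="leave_one_criterion_out")
        report = run_sensitivity(small_table, definitions=eco, scheme=scheme)
        assert report.n_draws == 4  # four weighted ecological criteria

    def test_is_deterministic_regardless_of_seed(self, small_table):
        a = run_sensitivity(small_table, scheme=PerturbationScheme(
            kind="leave_one_criterion_out", seed=1))
        b = run_sensitivity(small_table, scheme=PerturbationScheme(
            kind="leave_one_criterion_out", seed=99))
        assert a.priority_frequency == b.priority_frequency


def enumerate_flip_survival(weights, flip_p, threshold_num=1, threshold_den=2):
    """Exhaustive oracle: probability that an all-2 record stays at or above
    the priority threshold when each criterion independently drops one step
    with probability flip_p."""
    ids = list(weights)
    max_raw = 2 * sum(weights.values())
    survive = 0.0
    for mask in range(2 ** len(ids)):
        flipped = [ids[i] for i in range(len(ids)) if mask >> i & 1]
        prob = math.prod(flip_p if cid in flipped else 1 - flip_p for cid in ids)
        raw = max_raw - sum(weights[cid] for cid in flipped)
        if raw * threshold_den >= max_raw * threshold_num:
            survive += prob
    return survive


class TestResampleBehaviour:
    def test_confident_perfect_estuary_rarely_loses_priority(self):
        """An all-2, all-very-certain record keeps ecological priority under
        resampling; exhaustive enumeration of one-step flips gives the
        expected survival probability (here 1.0: even four simultaneous
        downgrades leave the score at the 11/22 boundary)."""
        eco = default_index_definitions()["ecological_priority"]
        record = make_record(default=0)
        for cid in eco.weights:
            record.scores[cid] = CriterionScore(2, certainty=3)
        expected = enumerate_flip_survival(dict(eco.weights), flip_p=0.02)
        scheme = PerturbationScheme(kind="score_resample", n_draws=2000, seed=7,
                                    flip_probabilities={3: 0.02})
        report = run_sensitivity([record], definitions={"ecological_priority": eco},
                                 scheme=scheme)
        freq = report.priority_frequency["ecological_priority"][record.name]
        assert expected == pytest.approx(1.0)
        assert freq >= 0.9
        assert abs(freq - expected) < 0.05

    def test_resampled_values_stay_on_scale_and_missing_untouched(self, small_table):
        from olyscore.sensitivity import _resample_records

        table = generate_table(GeneratorConfig(n_estuaries=10, seed=3))
        rng = np.random.default_rng(0)
        scheme = PerturbationScheme(flip_probabilities={1: 1.0, 2: 1.0, 3: 1.0, None: 1.0})
        perturbed = _resample_records(table, scheme, rng)
        for before, after in zip(table, perturbed):
            for cid in before.scores:
                b, a = before.scores[cid], after.scores[cid]
                assert a.is_missing == b.is_missing
                if not a.is_missing:
                    assert a.value in (0, 1, 2)
                    assert abs(a.value - b.value) == 1  # flip_p=1: always adjacent


class TestMonotoneConfidence:
    def test_raising_certainty_improves_stability(self):
        """With the default flip probabilities, an all-very-certain table is
        at least as stable (mean Jaccard to baseline) as the same table
        annotated all-not-very-certain, averaged over many seeds."""
        base = generate_table(GeneratorConfig(
            n_estuaries=6, core_all_missing_rate=0.0,
            missing_rate_by_region={r: 0.0 for r in ("BCC", "WA", "OR", "CA", "BCM")},
            seed=21))

        def with_certainty(level):
            out = []
            for rec in base:
                scores = {cid: CriterionScore(s.value, certainty=level)
                          for cid, s in rec.scores.items()}
                out.append(type(rec)(rec.name, rec.region, scores, rec.parent_system))
            return out

        eco = {"ecological_priority": default_index_definitions()["ecological_priority"]}
        means = {}
        for level in (1, 3):
            table = with_certainty(level)
            js = []
            for seed in range(20):
                scheme = PerturbationScheme(kind="score_resample", n_draws=500, seed=seed)
                report = run_sensitivity(table, definitions=eco, scheme=scheme)
                js.append(report.jaccard_mean["ecological_priority"])
            means[level] = sum(js) / len(js)
        assert means[3] >= means[1]
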