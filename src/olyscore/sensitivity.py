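"""Stability of the priority set under perturbation.

The scoring framework annotates every criterion score with an expert
certainty level but applies no quantitative uncertainty propagation. This
module supplies one: it perturbs inputs — resampling scores with
certainty-dependent flip probabilities, jittering integer weights, or
removing one criterion at a time — re-runs the full pipeline for each draw,
and reports how often each estuary remains a priority and how similar each
draw's priority set is to the baseline (Jaccard similarity).

The flip-probability mapping is module configuration, not an elicited error
model: the certainty stars carry no published numeric meaning, so any
stability claim must be reported together with the mapping that produced it.
Score resampling only moves to ordinally adjacent values (0<->1, 1<->2),
treating a one-step mis-score as the plausible expert error mode; MISSING
values are never resampled, so eligibility is invariant under perturbation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    ConfigurationError,
    CriterionScore,
    EstuaryRecord,
    IndexDefinition,
    default_index_definitions,
)
from .pipeline import EligibilityRule, filter_eligible, score_all

__all__ = [
    "PerturbationScheme",
    "StabilityReport",
    "run_sensitivity",
    "compare_priority_sets",
    "KINDS",
]

KINDS = ("score_resample", "weight_jitter", "leave_one_criterion_out")

#: Probability that a score one ordinal step off is recorded, by certainty
#: level; unannotated scores are treated like the least certain level.
DEFAULT_FLIP_PROBABILITIES: dict[Optional[int], float] = {
    1: 0.30,
    2: 0.10,
    3: 0.02,
    None: 0.30,
}


@dataclass(frozen=True)
class PerturbationScheme:
    """How to perturb inputs and how many Monte Carlo draws to take.

    ``weight_jitter_range`` is the maximum integer step added to or
    subtracted from each weight per draw (weights are floored at 1 so exact
    rational scoring stays valid). ``n_draws`` is ignored by the
    deterministic leave-one-criterion-out scheme.
    """

    kind: str = "score_resample"
    n_draws: int = 1000
    seed: int = 0
    flip_probabilities: Mapping[Optional[int], float] = field(
        default_factory=lambda: dict(DEFAULT_FLIP_PROBABILITIES))
    weight_jitter_range: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown perturbation kind {self.kind!r}")
        if self.n_draws < 1:
            raise ConfigurationError(f"n_draws must be >= 1, got {self.n_draws}")
        probs = dict(DEFAULT_FLIP_PROBABILITIES)
        probs.update(self.flip_probabilities)
        for level, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"flip probability for certainty {level!r} outside [0, 1]: {p}")
        object.__setattr__(self, "flip_probabilities", probs)
        if self.weight_jitter_range < 0:
            raise ConfigurationError("weight_jitter_range must be >= 0")


@dataclass
class StabilityReport:
    """Per-estuary priority frequencies and set-level stability statistics."""

    kind: str
    n_draws: int
    seed: int
    baseline_priority: dict[str, list[str]]
    priority_frequency: dict[str, dict[str, float]]
    jaccard_mean: dict[str, float]
    always_priority: dict[str, list[str]]
    never_priority: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "baseline_priority": {k: list(v) for k, v in self.baseline_priority.items()},
            "priority_frequency": {k: dict(v) for k, v in self.priority_frequency.items()},
            "jaccard_mean": dict(self.jaccard_mean),
            "always_priority": {k: list(v) for k, v in self.always_priority.items()},
            "never_priority": {k: list(v) for k, v in self.never_priority.items()},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def compare_priority_sets(a: set, b: set) -> float:
    """Jaccard similarity |a∩b| / |a∪b|; 1.0 when both sets are empty."""
    union = set(a) | set(b)
    if not union:
        return 1.0
    return len(set(a) & set(b)) / len(union)


def _flip_adjacent(value: int, rng: np.random.Generator) -> int:
    if value == 0:
        return 1
    if value == 2:
        return 1
    return 0 if rng.random() < 0.5 else 2


def _resample_records(records: Sequence[EstuaryRecord],
                      scheme: PerturbationScheme,
                      rng: np.random.Generator) -> list[EstuaryRecord]:
    probs = scheme.flip_probabilities
    out = []
    for rec in records:
        scores: dict[int, CriterionScore] = {}
        for cid, s in rec.scores.items():
            if s.is_missing:
                scores[cid] = s
                continue
            p = probs.get(s.certainty, probs[None])
            if p > 0 and rng.random() < p:
                scores[cid] = CriterionScore(_flip_adjacent(int(s.value), rng),
                                             certainty=s.certainty,
                                             rationale=s.rationale, sources=s.sources)
            else:
                scores[cid] = s
        out.append(EstuaryRecord(rec.name, rec.region, scores, rec.parent_system))
    return out


def _jitter_definitions(definitions: Mapping[str, IndexDefinition],
                        scheme: PerturbationScheme,
                        rng: np.random.Generator) -> dict[str, IndexDefinition]:
    step = scheme.weight_jitter_range
    out = {}
    for name, d in definitions.items():
        weights = {
            cid: max(1, w + int(rng.integers(-step, step + 1)))
            for cid, w in d.weights.items()
        }
        out[name] = IndexDefinition(name, weights, d.override_criteria, d.threshold)
    return out


def _loo_definitions(definition: IndexDefinition) -> list[IndexDefinition]:
    """One definition per weighted criterion, that criterion removed."""
    variants = []
    for drop in sorted(definition.weights):
        weights = {cid: w for cid, w in definition.weights.items() if cid != drop}
        if not weights:
            continue  # single-criterion index: nothing left to score
        override = definition.override_criteria - {drop}
        variants.append(IndexDefinition(definition.name, weights, override,
                                        definition.threshold))
    return variants


def _priority_sets(eligible: Sequence[EstuaryRecord],
                   definitions: Mapping[str, IndexDefinition]) -> dict[str, set]:
    sets: dict[str, set] = {name: set() for name in definitions}
    for r in score_all(eligible, definitions):
        if r.priority:
            sets[r.index].add(r.estuary)
    return sets


def run_sensitivity(records: Sequence[EstuaryRecord],
                    definitions: Optional[Mapping[str, IndexDefinition]] = None,
                    rule: Optional[EligibilityRule] = None,
                    scheme: Optional[PerturbationScheme] = None) -> StabilityReport:
    """Perturb, re-score, and summarize priority-set stability.

    All randomness comes from one :func:`numpy.random.default_rng` seeded by
    ``scheme.seed``; identical inputs and scheme give identical reports.
    """
    definitions = definitions if definitions is not None else default_index_definitions()
    scheme = scheme or PerturbationScheme()
    eligible, _ = filter_eligible(records, rule)
    names = [r.name for r in eligible]

    baseline = _priority_sets(eligible, definitions)
    rng = np.random.default_rng(scheme.seed)

    counts: dict[str, dict[str, int]] = {
        idx: {n: 0 for n in names} for idx in definitions}
    jaccard_sums: dict[str, float] = {idx: 0.0 for idx in definitions}
    draws_per_index: dict[str, int] = {idx: 0 for idx in definitions}

    def record_draw(index_name: str, prio: set) -> None:
        draws_per_index[index_name] += 1
        jaccard_sums[index_name] += compare_priority_sets(prio, baseline[index_name])
        for n in prio:
            counts[index_name][n] += 1

    if scheme.kind == "leave_one_criterion_out":
        for name, definition in definitions.items():
            for variant in _loo_definitions(definition):
                prio = _priority_sets(eligible, {name: variant})[name]
                record_draw(name, prio)
    else:
        for _ in range(scheme.n_draws):
            if scheme.kind == "score_resample":
                draw_records = _resample_records(eligible, scheme, rng)
                draw_defs: Mapping[str, IndexDefinition] = definitions
            else:  # weight_jitter
                draw_records = list(eligible)
                draw_defs = _jitter_definitions(definitions, scheme, rng)
            for name, prio in _priority_sets(draw_records, draw_defs).items():
                record_draw(name, prio)

    frequency = {
        idx: {n: counts[idx][n] / max(draws_per_index[idx], 1) for n in names}
        for idx in definitions
    }
    return StabilityReport(
        kind=scheme.kind,
        n_draws=max(draws_per_index.values()) if draws_per_index else 0,
        seed=scheme.seed,
        baseline_priority={idx: sorted(s) for idx, s in baseline.items()},
        priority_frequency=frequency,
        jaccard_mean={
            idx: jaccard_sums[idx] / max(draws_per_index[idx], 1) for idx in definitions},
        always_priority={
            idx: sorted(n for n in names if frequency[idx][n] == 1.0) for idx in definitions},
        never_priority={
            idx: sorted(n for n in names if frequency[idx][n] == 0.0) for idx in definitions},
    )
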