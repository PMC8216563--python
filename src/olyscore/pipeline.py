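"""Eligibility filtering, batch scoring, ranking and report generation.

The pipeline mirrors the study workflow: records lacking data on the three
fundamental ecological criteria (recruitment, extinction risk, post-settlement
mortality) are set aside; every remaining estuary is scored against every
index; estuaries at or above an index threshold are flagged as priorities;
and results are summarized as ranked lists, priority counts, score bands, and
an estuary-by-index matrix (rows in input, i.e. north-to-south, order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import (
    Criterion,
    EstuaryRecord,
    IndexDefinition,
    IndexResult,
    classify_priority,
    default_criteria,
    default_index_definitions,
    score_record,
)

__all__ = [
    "EligibilityRule",
    "RunSummary",
    "filter_eligible",
    "score_all",
    "rank_results",
    "summarize_run",
    "render_index_matrix",
    "results_to_frame",
]

#: Ecological index band edge used in reporting: scores strictly above this
#: (but below the maximum) are reported as a distinct high band.
HIGH_BAND_EDGE = Fraction(7, 10)


@dataclass(frozen=True)
class EligibilityRule:
    """Which records are scored at all.

    With the default ``all_missing`` mode a record is excluded only when every
    core criterion (1-3) is MISSING; ``any_missing`` excludes a record missing
    any of them.
    """

    core_criteria: frozenset[int] = frozenset({1, 2, 3})
    mode: str = "all_missing"

    def __post_init__(self) -> None:
        if not self.core_criteria:
            raise ValueError("core_criteria must be non-empty")
        if self.mode not in ("all_missing", "any_missing"):
            raise ValueError(f"unknown eligibility mode {self.mode!r}")
        object.__setattr__(self, "core_criteria", frozenset(self.core_criteria))

    def excludes(self, record: EstuaryRecord) -> bool:
        missing = [record.score(cid).is_missing for cid in sorted(self.core_criteria)]
        return all(missing) if self.mode == "all_missing" else any(missing)


def filter_eligible(records: Sequence[EstuaryRecord],
                    rule: Optional[EligibilityRule] = None
                    ) -> tuple[list[EstuaryRecord], list[EstuaryRecord]]:
    """Partition records into (eligible, excluded), both in input order."""
    rule = rule or EligibilityRule()
    eligible, excluded = [], []
    for rec in records:
        (excluded if rule.excludes(rec) else eligible).append(rec)
    return eligible, excluded


def score_all(eligible: Sequence[EstuaryRecord],
              definitions: Optional[Mapping[str, IndexDefinition]] = None,
              criteria: Optional[Sequence[Criterion]] = None) -> list[IndexResult]:
    """Score every record against every index: one IndexResult per pair."""
    definitions = definitions if definitions is not None else default_index_definitions()
    registry = list(criteria) if criteria is not None else None
    return [
        score_record(rec, definition, eligible=True, registry=registry)
        for rec in eligible
        for definition in definitions.values()
    ]


def rank_results(results: Sequence[IndexResult], index_name: str) -> list[IndexResult]:
    """Results for one index, best first.

    Descending score; ties broken by fewer missing weighted criteria, then
    estuary name ascending — a total, deterministic order.
    """
    subset = [r for r in results if r.index == index_name]
    if not subset:
        raise KeyError(f"no results for index {index_name!r}")
    return sorted(subset, key=lambda r: (-r.score, r.n_missing_weighted, r.estuary))


@dataclass
class RunSummary:
    """Counts and priority lists for a full scoring run.

    ``project_type_among_priorities`` counts, among the *ecological-priority*
    estuaries only, how many meet each project-type index threshold — the
    framing used when asking what kind of aquaculture project suits the
    priority estuaries. ``bands`` reports, per index over all eligible
    estuaries, how many score strictly above the high band edge (0.7) without
    reaching the maximum, and how many score exactly 1.
    """

    n_input: int
    n_eligible: int
    n_excluded: int
    n_priority: dict[str, int] = field(default_factory=dict)
    priority_estuaries: dict[str, list[str]] = field(default_factory=dict)
    project_type_among_priorities: dict[str, int] = field(default_factory=dict)
    bands: dict[str, dict[str, int]] = field(default_factory=dict)
    excluded_estuaries: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "n_excluded": self.n_excluded,
            "n_priority": dict(self.n_priority),
            "priority_estuaries": {k: list(v) for k, v in self.priority_estuaries.items()},
            "project_type_among_priorities": dict(self.project_type_among_priorities),
            "bands": {k: dict(v) for k, v in self.bands.items()},
            "excluded_estuaries": list(self.excluded_estuaries),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


ECOLOGICAL_INDEX = "ecological_priority"


def summarize_run(records: Sequence[EstuaryRecord],
                  definitions: Optional[Mapping[str, IndexDefinition]] = None,
                  rule: Optional[EligibilityRule] = None,
                  criteria: Optional[Sequence[Criterion]] = None) -> RunSummary:
    """Run eligibility + scoring and distil the headline counts."""
    definitions = definitions if definitions is not None else default_index_definitions()
    eligible, excluded = filter_eligible(records, rule)
    results = score_all(eligible, definitions, criteria)

    summary = RunSummary(
        n_input=len(records),
        n_eligible=len(eligible),
        n_excluded=len(excluded),
        excluded_estuaries=[r.name for r in excluded],
    )

    by_index: dict[str, list[IndexResult]] = {name: [] for name in definitions}
    for r in results:
        by_index[r.index].append(r)

    for name, subset in by_index.items():
        prios = [r for r in subset if r.priority]
        ranked = sorted(prios, key=lambda r: (-r.score, r.n_missing_weighted, r.estuary))
        summary.n_priority[name] = len(prios)
        summary.priority_estuaries[name] = [r.estuary for r in ranked]
        summary.bands[name] = {
            "above_0_7": sum(1 for r in subset if HIGH_BAND_EDGE < r.score < 1),
            "exact_max": sum(1 for r in subset if r.score == 1),
        }

    eco_priorities = set(summary.priority_estuaries.get(ECOLOGICAL_INDEX, []))
    for name, definition in definitions.items():
        if name == ECOLOGICAL_INDEX:
            continue
        summary.project_type_among_priorities[name] = sum(
            1 for r in by_index[name]
            if r.estuary in eco_priorities
            and classify_priority(r.score, definition.threshold)
        )
    return summary


def results_to_frame(results: Sequence[IndexResult]) -> pd.DataFrame:
    """Long-form results table: one row per (estuary, index)."""
    return pd.DataFrame(
        {
            "estuary": r.estuary,
            "index": r.index,
            "raw": r.raw,
            "max_raw": r.max_raw,
            "score": f"{float(r.score):.4f}",
            "score_exact": f"{r.score.numerator}/{r.score.denominator}",
            "override_applied": r.override_applied,
            "priority": r.priority,
            "n_missing_weighted": r.n_missing_weighted,
        }
        for r in results
    )


def render_index_matrix(records: Sequence[EstuaryRecord],
                        results: Sequence[IndexResult],
                        definitions: Optional[Mapping[str, IndexDefinition]] = None,
                        criteria: Optional[Sequence[Criterion]] = None) -> pd.DataFrame:
    """Estuary-by-index matrix with per-criterion values, input order.

    One row per scored estuary: name, region, one column per index with the
    score displayed to two decimals (display only — classification always
    uses the exact rationals), then the 14 criterion values with MISSING as
    a null (empty in CSV, ``null`` in JSON, never 0).
    """
    definitions = definitions if definitions is not None else default_index_definitions()
    criteria = list(criteria) if criteria is not None else default_criteria()
    scored = {(r.estuary, r.index): r for r in results}
    scored_names = {r.estuary for r in results}

    rows = []
    for rec in records:
        if rec.name not in scored_names:
            continue
        row: dict = {"estuary": rec.name, "region": rec.region}
        for name in definitions:
            row[name] = f"{float(scored[(rec.name, name)].score):.2f}"
        for c in criteria:
            s = rec.score(c.id)
            row[c.key] = pd.NA if s.is_missing else s.value
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame[[c.key for c in criteria]] = frame[[c.key for c in criteria]].astype("Int64")
    return frame


def write_run_outputs(out_dir: Union[str, Path],
                      records: Sequence[EstuaryRecord],
                      definitions: Optional[Mapping[str, IndexDefinition]] = None,
                      rule: Optional[EligibilityRule] = None) -> dict[str, Path]:
    """Score a table and write results.csv, matrix.csv and summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    definitions = definitions if definitions is not None else default_index_definitions()
    eligible, _ = filter_eligible(records, rule)
    results = score_all(eligible, definitions)
    summary = summarize_run(records, definitions, rule)

    paths = {
        "results": out_dir / "results.csv",
        "matrix": out_dir / "matrix.csv",
        "summary": out_dir / "summary.json",
    }
    results_to_frame(results).to_csv(paths["results"], index=False)
    render_index_matrix(records, results, definitions).to_csv(paths["matrix"], index=False)
    paths["summary"].write_text(summary.to_json() + "\n", encoding="utf-8")
    return paths
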