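"""Domain types and exact scoring arithmetic for estuary prioritization indices.

The framework evaluates estuaries for Olympia oyster (*Ostrea lurida*)
conservation aquaculture using 14 expert-scored criteria. Each criterion is
answered on an ordinal 0/1/2 scale (0 = low, 1 = medium, 2 = high priority for
aquaculture investment), optionally annotated with a 1-3 certainty level.
Four named indices combine subsets of the criteria with positive integer
weights; each index is the weighted criterion sum divided by its maximum
possible value, so scores lie in [0, 1]. Two indices carry veto ("override")
criteria whose zero value forces the index to 0 regardless of other scores.

All score arithmetic is exact: raw sums are integers and normalized scores
are :class:`fractions.Fraction` values, so the priority boundary (score equal
to the threshold, e.g. 11/22 against 1/2) classifies deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "MISSING",
    "REGIONS",
    "Criterion",
    "CriterionScore",
    "EstuaryRecord",
    "IndexDefinition",
    "IndexResult",
    "ConfigurationError",
    "ScoreValidationError",
    "default_criteria",
    "default_index_definitions",
    "effective_value",
    "weighted_raw_score",
    "override_triggered",
    "normalized_index",
    "classify_priority",
    "score_record",
    "as_fraction",
]

#: Region codes ordered north to south along the species range.
REGIONS = ("BCC", "WA", "OR", "CA", "BCM")


class ConfigurationError(ValueError):
    """An index definition or configuration document is invalid."""


class ScoreValidationError(ValueError):
    """A criterion score or record violates the ordinal scoring scale."""


class _Missing:
    """Singleton marking an unscored criterion (distinct from an assigned 0).

    Missingness matters for eligibility filtering and reporting even though
    the scoring rule treats missing values as zero.
    """

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

ScoreValue = Union[int, _Missing]


@dataclass(frozen=True)
class Criterion:
    """One of the 14 evaluation questions.

    Parameters
    ----------
    id : int
        Position in the canonical criteria table (1-14 for the defaults).
    key : str
        Short machine token, e.g. ``"recruitment"`` or ``"safe_to_eat"``.
    question : str
        The criterion phrased as a question to the scorer.
    rationale : str
        Why the criterion enters the evaluation.
    """

    id: int
    key: str
    question: str = ""
    rationale: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.id, int) or self.id < 1:
            raise ScoreValidationError(f"criterion id must be a positive integer, got {self.id!r}")
        if not self.key:
            raise ScoreValidationError("criterion key must be non-empty")


@dataclass(frozen=True)
class CriterionScore:
    """An ordinal score 0/1/2 or MISSING, with optional certainty annotation.

    ``certainty`` encodes the scorers' confidence: 1 = not very certain (*),
    2 = fairly certain (**), 3 = very certain (***). It never enters the
    index arithmetic; it is metadata consumed by reporting and by the
    sensitivity machinery.
    """

    value: ScoreValue = MISSING
    certainty: Optional[int] = None
    rationale: str = ""
    sources: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.value, _Missing):
            if not isinstance(self.value, int) or isinstance(self.value, bool) or self.value not in (0, 1, 2):
                raise ScoreValidationError(
                    f"criterion score must be 0, 1, 2 or MISSING, got {self.value!r}"
                )
        if self.certainty is not None and self.certainty not in (1, 2, 3):
            raise ScoreValidationError(
                f"certainty must be 1, 2, 3 or None, got {self.certainty!r}"
            )

    @property
    def is_missing(self) -> bool:
        return isinstance(self.value, _Missing)

    @property
    def effective(self) -> int:
        """The value the scoring rule uses: missing data count as zero."""
        return 0 if self.is_missing else int(self.value)  # type: ignore[arg-type]


@dataclass
class EstuaryRecord:
    """A named estuary (or sub-basin treated as an estuary) and its scores.

    Sub-basins of large systems (Salish Sea, San Francisco Bay) are
    independent records; ``parent_system`` names the enclosing system for
    reporting only — no aggregation across it ever occurs.
    """

    name: str
    region: str
    scores: dict[int, CriterionScore] = field(default_factory=dict)
    parent_system: Optional[str] = None

    def score(self, criterion_id: int) -> CriterionScore:
        """The score for a criterion; absent entries read as MISSING."""
        return self.scores.get(criterion_id, CriterionScore(MISSING))


@dataclass(frozen=True)
class IndexDefinition:
    """A named weighted-sum index over a subset of criteria.

    ``weights`` maps criterion id to a strictly positive integer weight;
    criteria absent from the mapping contribute nothing. ``override_criteria``
    is the veto set: an effective zero on any member forces the index to 0.
    ``threshold`` is the priority cut-off, compared exactly (default 1/2).
    """

    name: str
    weights: Mapping[int, int]
    override_criteria: frozenset[int] = frozenset()
    threshold: Fraction = Fraction(1, 2)

    def __post_init__(self) -> None:
        if not self.weights:
            raise ConfigurationError(f"index {self.name!r}: weights mapping is empty")
        for cid, w in self.weights.items():
            if not isinstance(w, int) or isinstance(w, bool) or w <= 0:
                raise ConfigurationError(
                    f"index {self.name!r}: weight for criterion {cid} must be a "
                    f"positive integer, got {w!r}"
                )
        object.__setattr__(self, "weights", dict(self.weights))
        object.__setattr__(self, "override_criteria", frozenset(self.override_criteria))
        extra = self.override_criteria - set(self.weights)
        if extra:
            raise ConfigurationError(
                f"index {self.name!r}: override criteria {sorted(extra)} are not in "
                "the weight mapping"
            )
        thr = as_fraction(self.threshold)
        if not (0 < thr <= 1):
            raise ConfigurationError(
                f"index {self.name!r}: threshold must lie in (0, 1], got {thr}"
            )
        object.__setattr__(self, "threshold", thr)

    @property
    def max_raw(self) -> int:
        """Maximum attainable weighted sum: every weighted criterion at 2."""
        return 2 * sum(self.weights.values())


@dataclass(frozen=True)
class IndexResult:
    """The outcome of scoring one estuary against one index."""

    estuary: str
    index: str
    raw: int
    max_raw: int
    score: Fraction
    eligible: bool
    override_applied: bool
    priority: bool
    n_missing_weighted: int


def as_fraction(x: Union[Rational, float, str]) -> Fraction:
    """Convert a numeric threshold to an exact Fraction.

    Floats are interpreted through their shortest decimal representation
    (0.5 -> 1/2, 0.7 -> 7/10), so decimal text survives exactly even when an
    upstream parser produced a binary float.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


_DEFAULT_CRITERIA: tuple[Criterion, ...] = (
    Criterion(1, "recruitment", "Is recruitment limited?",
              "Aquaculture can make the biggest difference where low recruitment "
              "chronically limits the population."),
    Criterion(2, "extinction_risk", "Is the population at risk of local extinction?",
              "Very small adult populations at risk of disappearing benefit most "
              "from supplementation."),
    Criterion(3, "mortality", "Is post-settlement mortality low?",
              "Return on investment is highest where outplanted juveniles survive; "
              "avoid sites with heavy drill predation or freshwater kills."),
    Criterion(4, "isolation", "How isolated is this population?",
              "Populations without larval exchange from neighbours are vulnerable "
              "to total loss and gain more from intervention."),
    Criterion(5, "hatchery", "Is there a nearby conservation hatchery with local broodstock?",
              "A local hatchery avoids the pathogen, parasite and fouling risks of "
              "shipping spat, and conservation protocols retain local genetics."),
    Criterion(6, "safe_to_eat", "Is it safe to eat shellfish here?",
              "Water quality must allow safe consumption before any harvest or "
              "commercial production can be considered."),
    Criterion(7, "harvest_regulations", "Do regulations allow harvest of Olympia oysters?",
              "Community harvest projects require that harvest be legal."),
    Criterion(8, "growth", "Is post-settlement growth high?",
              "Fast growth shortens the time from outplant to harvestable size."),
    Criterion(9, "bivalves_farmed", "Are bivalves currently farmed in this estuary?",
              "Existing farming infrastructure and a water-quality track record "
              "ease new or expanded native-oyster aquaculture."),
    Criterion(10, "management_plan", "Is native oyster restoration in local management plans?",
              "Permitting and investment are easier where organizations have "
              "already identified restoration as a priority."),
    Criterion(11, "community_oyster_restoration",
              "Are community groups engaged in Olympia oyster restoration?",
              "Engaged communities raise the odds that aquaculture-based "
              "restoration succeeds and benefits people."),
    Criterion(12, "community_bivalve_restoration",
              "Are community groups restoring other bivalve species?",
              "Groups working on similar species signal capacity and interest for "
              "future native-oyster work."),
    Criterion(13, "tribes_first_nations",
              "Are Tribes or First Nations engaged in shellfish restoration or wild harvest?",
              "Indigenous stewardship sustains long-term restoration and cultural "
              "harvest practices, and raises the priority of enabling them."),
    Criterion(14, "community_grow_harvest",
              "Are non-commercial community groups growing shellfish for harvest?",
              "Groups that already grow and harvest shellfish strengthen "
              "stewardship and maintenance of oyster beds."),
)


def default_criteria() -> list[Criterion]:
    """The canonical 14-criterion registry, in table order (ids 1-14)."""
    return list(_DEFAULT_CRITERIA)


def default_index_definitions() -> dict[str, IndexDefinition]:
    """The four standard indices with their published weights and vetoes.

    Ecological priority uses only the four ecological criteria (recruitment
    weighted highest). The three project-type indices all include
    post-settlement mortality plus differing social/logistic criteria.
    Community harvest is vetoed by unsafe consumption or illegal harvest;
    commercial production by unsafe consumption alone.
    """
    return {
        "ecological_priority": IndexDefinition(
            "ecological_priority", {1: 4, 2: 3, 3: 2, 4: 2}),
        "community_restoration": IndexDefinition(
            "community_restoration", {3: 2, 5: 1, 10: 2, 11: 2, 12: 1, 13: 1}),
        "community_harvest": IndexDefinition(
            "community_harvest", {3: 2, 5: 1, 6: 3, 7: 2, 8: 1, 9: 1, 13: 1, 14: 1},
            override_criteria=frozenset({6, 7})),
        "commercial_production": IndexDefinition(
            "commercial_production", {3: 1, 5: 2, 6: 3, 8: 1, 9: 1, 14: 1},
            override_criteria=frozenset({6})),
    }


_DEFAULT_IDS = frozenset(c.id for c in _DEFAULT_CRITERIA)


def _check_definition_ids(definition: IndexDefinition,
                          registry: Optional[Iterable[Criterion]]) -> None:
    known = _DEFAULT_IDS if registry is None else {c.id for c in registry}
    unknown = set(definition.weights) - known
    if unknown:
        raise ConfigurationError(
            f"index {definition.name!r} references unknown criterion ids "
            f"{sorted(unknown)}"
        )


def effective_value(record: EstuaryRecord, criterion_id: int) -> int:
    """Score value entering the sums: MISSING and absent both count as 0."""
    return record.score(criterion_id).effective


def weighted_raw_score(record: EstuaryRecord, definition: IndexDefinition,
                       registry: Optional[Iterable[Criterion]] = None) -> int:
    """Weighted sum of effective criterion values for one index.

    Certainty annotations never enter the sum. Raises
    :class:`ConfigurationError` if the definition references a criterion id
    outside the registry (default registry when none is given).
    """
    _check_definition_ids(definition, registry)
    return sum(w * record.score(cid).effective for cid, w in definition.weights.items())


def override_triggered(record: EstuaryRecord, definition: IndexDefinition) -> bool:
    """True iff any veto criterion has effective value 0.

    An explicit 0 and a MISSING value both trigger the veto, consistent with
    the missing-data-counts-as-zero scoring rule.
    """
    return any(record.score(cid).effective == 0 for cid in definition.override_criteria)


def normalized_index(record: EstuaryRecord, definition: IndexDefinition,
                     registry: Optional[Iterable[Criterion]] = None) -> Fraction:
    """Index score in [0, 1]: raw/max_raw, or exactly 0 under a veto."""
    if override_triggered(record, definition):
        _check_definition_ids(definition, registry)
        return Fraction(0)
    return Fraction(weighted_raw_score(record, definition, registry), definition.max_raw)


def classify_priority(score: Union[Rational, float], threshold: Union[Rational, float]) -> bool:
    """True iff score >= threshold, exact at the boundary.

    Both operands are compared as exact rationals, so a raw/max ratio equal
    to the threshold (e.g. 11/22 against 0.50) always classifies as priority.
    """
    return as_fraction(score) >= as_fraction(threshold)


def score_record(record: EstuaryRecord, definition: IndexDefinition,
                 eligible: bool = True,
                 registry: Optional[Iterable[Criterion]] = None) -> IndexResult:
    """Score one record against one index, producing a full IndexResult."""
    override = override_triggered(record, definition)
    raw = weighted_raw_score(record, definition, registry)
    score = Fraction(0) if override else Fraction(raw, definition.max_raw)
    n_missing = sum(1 for cid in definition.weights if record.score(cid).is_missing)
    priority = eligible and classify_priority(score, definition.threshold)
    return IndexResult(
        estuary=record.name,
        index=definition.name,
        raw=raw,
        max_raw=definition.max_raw,
        score=score,
        eligible=eligible,
        override_applied=override,
        priority=priority,
        n_missing_weighted=n_missing,
    )
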