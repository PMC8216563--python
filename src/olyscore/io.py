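"""Reading, writing and validating score tables and index configuration.

The canonical on-disk score table is UTF-8 CSV: one row per estuary, with
name/region/parent columns followed by one score column per criterion and,
optionally, companion certainty / rationale / sources columns. Spreadsheet
workbooks (.xlsx) are supported read-only as a convenience for users holding
an original scoring workbook; only cell values are read, never formulas.

A :class:`ScoreTableDialect` maps criterion keys to column headers so a table
with foreign headers can be ingested without code changes.

Index configuration is a YAML/JSON document::

    indices:
      ecological_priority:
        weights: {recruitment: 4, extinction_risk: 3, mortality: 2, isolation: 2}
        threshold: 0.5
      community_harvest:
        override: [safe_to_eat, harvest_regulations]

Anything absent falls back to the built-in defaults. Thresholds written as
decimal text become exact rationals (0.50 -> 1/2) so boundary classification
stays deterministic.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .core import (
    MISSING,
    REGIONS,
    ConfigurationError,
    Criterion,
    CriterionScore,
    EstuaryRecord,
    IndexDefinition,
    as_fraction,
    default_criteria,
    default_index_definitions,
)

__all__ = [
    "ScoreTableDialect",
    "ValidationIssue",
    "TableFormatError",
    "read_score_table",
    "write_score_table",
    "read_index_config",
    "validate_table",
]

DEFAULT_MISSING_TOKENS = frozenset({"", "unknown", "NA", "?"})

_CERTAINTY_STARS = {"*": 1, "**": 2, "***": 3}


class TableFormatError(ValueError):
    """The score table file violates the expected layout or scale."""


@dataclass(frozen=True)
class ValidationIssue:
    """A problem found in a table: errors block scoring, warnings do not."""

    severity: str  # "error" | "warning"
    message: str
    estuary: Optional[str] = None
    criterion: Optional[int] = None

    def __str__(self) -> str:
        loc = []
        if self.estuary is not None:
            loc.append(f"estuary={self.estuary!r}")
        if self.criterion is not None:
            loc.append(f"criterion={self.criterion}")
        where = f" [{', '.join(loc)}]" if loc else ""
        return f"{self.severity.upper()}{where}: {self.message}"


@dataclass(frozen=True)
class ScoreTableDialect:
    """Column layout of a score table.

    ``score_columns`` maps criterion key -> column header. Certainty,
    rationale and sources columns are the score header plus the respective
    suffix. Cell values in ``missing_tokens`` parse as MISSING.
    """

    score_columns: Mapping[str, str] = field(
        default_factory=lambda: {c.key: c.key for c in default_criteria()})
    certainty_suffix: str = "_certainty"
    rationale_suffix: str = "_rationale"
    sources_suffix: str = "_sources"
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS
    name_column: str = "estuary"
    region_column: str = "region"
    parent_column: str = "parent_system"

    def __post_init__(self) -> None:
        headers = list(self.score_columns.values())
        if len(set(headers)) != len(headers):
            raise ConfigurationError("dialect maps two criteria to the same header")
        object.__setattr__(self, "score_columns", dict(self.score_columns))
        object.__setattr__(self, "missing_tokens", frozenset(self.missing_tokens))


def _parse_score_cell(cell: str, dialect: ScoreTableDialect):
    text = cell.strip()
    if text in dialect.missing_tokens:
        return MISSING
    if text in ("0", "1", "2"):
        return int(text)
    raise TableFormatError(f"score cell {cell!r} is not 0, 1, 2 or a missing token")


def _parse_certainty_cell(cell: str) -> Optional[int]:
    text = cell.strip()
    if text == "":
        return None
    if text in _CERTAINTY_STARS:
        return _CERTAINTY_STARS[text]
    if text in ("1", "2", "3"):
        return int(text)
    raise TableFormatError(f"certainty cell {cell!r} is not 1-3 or */**/***")


def _rows_from_csv(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row]
    if not rows:
        raise TableFormatError(f"{path}: empty file, header row required")
    return rows[0], rows[1:]


def _rows_from_workbook(path: Path) -> tuple[list[str], list[list[str]]]:
    # values only: formulas in the workbook are never evaluated or trusted
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    raw = [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
    wb.close()
    raw = [r for r in raw if any(cell.strip() for cell in r)]
    if not raw:
        raise TableFormatError(f"{path}: empty worksheet, header row required")
    return raw[0], raw[1:]


def read_score_table(path: Union[str, Path],
                     dialect: Optional[ScoreTableDialect] = None,
                     criteria: Optional[Sequence[Criterion]] = None) -> list[EstuaryRecord]:
    """Parse a CSV or .xlsx score table into estuary records, in file order.

    Raises :class:`TableFormatError` naming the row and column for any cell
    outside the 0-2 scale, and for duplicate estuary names. Unrecognized
    headers produce a warning and are ignored.
    """
    path = Path(path)
    dialect = dialect or ScoreTableDialect()
    criteria = list(criteria) if criteria is not None else default_criteria()
    key_to_id = {c.key: c.id for c in criteria}

    if path.suffix.lower() in (".xlsx", ".xlsm"):
        header, data_rows = _rows_from_workbook(path)
    else:
        header, data_rows = _rows_from_csv(path)
    header = [h.strip() for h in header]
    col_of = {h: i for i, h in enumerate(header)}

    known: set[str] = {dialect.name_column, dialect.region_column, dialect.parent_column}
    score_col: dict[int, int] = {}
    aux_col: dict[tuple[int, str], int] = {}
    for key, head in dialect.score_columns.items():
        cid = key_to_id.get(key)
        if cid is None:
            raise ConfigurationError(f"dialect maps unknown criterion key {key!r}")
        known.add(head)
        if head in col_of:
            score_col[cid] = col_of[head]
        for kind, suffix in (("certainty", dialect.certainty_suffix),
                             ("rationale", dialect.rationale_suffix),
                             ("sources", dialect.sources_suffix)):
            aux = head + suffix
            known.add(aux)
            if aux in col_of:
                aux_col[(cid, kind)] = col_of[aux]
    for h in header:
        if h not in known:
            warnings.warn(f"{path.name}: ignoring unrecognized column {h!r}", stacklevel=2)

    if dialect.name_column not in col_of:
        raise TableFormatError(f"{path}: missing required column {dialect.name_column!r}")

    def cell(row: list[str], idx: Optional[int]) -> str:
        if idx is None or idx >= len(row):
            return ""
        return row[idx]

    records: list[EstuaryRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(data_rows, start=2):
        name = cell(row, col_of[dialect.name_column]).strip()
        if not name:
            raise TableFormatError(f"{path}: row {rownum}: empty estuary name")
        if name in seen:
            raise TableFormatError(f"{path}: row {rownum}: duplicate estuary name {name!r}")
        seen.add(name)
        region = cell(row, col_of.get(dialect.region_column)).strip()
        parent = cell(row, col_of.get(dialect.parent_column)).strip() or None
        scores: dict[int, CriterionScore] = {}
        for cid, idx in score_col.items():
            try:
                value = _parse_score_cell(cell(row, idx), dialect)
                certainty = _parse_certainty_cell(cell(row, aux_col.get((cid, "certainty"))))
            except TableFormatError as exc:
                raise TableFormatError(
                    f"{path}: row {rownum}, column {header[idx]!r}: {exc}") from exc
            scores[cid] = CriterionScore(
                value=value,
                certainty=certainty,
                rationale=cell(row, aux_col.get((cid, "rationale"))),
                sources=cell(row, aux_col.get((cid, "sources"))),
            )
        records.append(EstuaryRecord(name=name, region=region, scores=scores,
                                     parent_system=parent))
    return records


def write_score_table(records: Iterable[EstuaryRecord],
                      path: Union[str, Path],
                      dialect: Optional[ScoreTableDialect] = None,
                      criteria: Optional[Sequence[Criterion]] = None) -> Path:
    """Write records as CSV; round-trips exactly through read_score_table.

    Columns follow criterion id order. MISSING scores are written as the
    empty cell; certainty is always written as an integer 1-3.
    """
    path = Path(path)
    dialect = dialect or ScoreTableDialect()
    criteria = list(criteria) if criteria is not None else default_criteria()
    records = list(records)

    header = [dialect.name_column, dialect.region_column, dialect.parent_column]
    write_aux = {
        "rationale": any(r.score(c.id).rationale for r in records for c in criteria),
        "sources": any(r.score(c.id).sources for r in records for c in criteria),
    }
    for c in criteria:
        head = dialect.score_columns.get(c.key, c.key)
        header.append(head)
        header.append(head + dialect.certainty_suffix)
        if write_aux["rationale"]:
            header.append(head + dialect.rationale_suffix)
        if write_aux["sources"]:
            header.append(head + dialect.sources_suffix)

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row: list[str] = [rec.name, rec.region, rec.parent_system or ""]
            for c in criteria:
                s = rec.score(c.id)
                row.append("" if s.is_missing else str(s.value))
                row.append("" if s.certainty is None else str(s.certainty))
                if write_aux["rationale"]:
                    row.append(s.rationale)
                if write_aux["sources"]:
                    row.append(s.sources)
            writer.writerow(row)
    return path


def _coerce_weight(value, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ConfigurationError(f"{where}: weight must be a positive integer, got {value!r}")
    if value <= 0:
        raise ConfigurationError(f"{where}: weight must be strictly positive, got {value}")
    return value


def _resolve_criterion(token, key_to_id: Mapping[str, int], where: str) -> int:
    if isinstance(token, int) and not isinstance(token, bool):
        if token in key_to_id.values():
            return token
        raise ConfigurationError(f"{where}: unknown criterion id {token}")
    if isinstance(token, str):
        if token in key_to_id:
            return key_to_id[token]
        if token.isdigit() and int(token) in key_to_id.values():
            return int(token)
        raise ConfigurationError(f"{where}: unknown criterion key {token!r}")
    raise ConfigurationError(f"{where}: cannot interpret criterion {token!r}")


def read_index_config(path: Optional[Union[str, Path]] = None,
                      criteria: Optional[Sequence[Criterion]] = None
                      ) -> dict[str, IndexDefinition]:
    """Load index definitions from YAML/JSON; anything absent uses defaults.

    Weight maps may be keyed by criterion key or id. A listed index with no
    weights inherits the default weights for that index name (overrides and
    threshold may still be customized); an unknown index name must supply
    weights.
    """
    criteria = list(criteria) if criteria is not None else default_criteria()
    key_to_id = {c.key: c.id for c in criteria}
    defaults = default_index_definitions()
    if path is None:
        return defaults
    path = Path(path)
    if not path.exists():
        return defaults

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return defaults
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    entries = doc.get("indices", {})
    if not isinstance(entries, dict):
        raise ConfigurationError(f"{path}: 'indices' must be a mapping")

    definitions = dict(defaults)
    for name, body in entries.items():
        body = body or {}
        if not isinstance(body, dict):
            raise ConfigurationError(f"{path}: index {name!r} must be a mapping")
        base = defaults.get(name)
        where = f"{path}: index {name!r}"

        if "weights" in body:
            weights = {
                _resolve_criterion(tok, key_to_id, where): _coerce_weight(w, where)
                for tok, w in body["weights"].items()
            }
        elif base is not None:
            weights = dict(base.weights)
        else:
            raise ConfigurationError(f"{where}: unknown index requires explicit weights")

        if "override" in body:
            override = frozenset(
                _resolve_criterion(tok, key_to_id, where) for tok in (body["override"] or []))
        elif base is not None:
            override = base.override_criteria
        else:
            override = frozenset()

        if "threshold" in body:
            threshold = as_fraction(body["threshold"])
        elif base is not None:
            threshold = base.threshold
        else:
            threshold = as_fraction("0.5")

        try:
            definitions[name] = IndexDefinition(name, weights, override, threshold)
        except ConfigurationError as exc:
            raise ConfigurationError(f"{where}: {exc}") from exc
    return definitions


def validate_table(records: Sequence[EstuaryRecord],
                   definitions: Optional[Mapping[str, IndexDefinition]] = None,
                   criteria: Optional[Sequence[Criterion]] = None) -> list[ValidationIssue]:
    """Check a parsed table; returns issues rather than raising.

    Errors: duplicate names, scores outside the 0-2 scale, unregistered
    criterion ids. Warnings: MISSING values on criteria weighted by an active
    index (including the eligibility-critical first three), unknown region
    codes, and scored values lacking a certainty annotation.
    """
    definitions = definitions if definitions is not None else default_index_definitions()
    criteria = list(criteria) if criteria is not None else default_criteria()
    known_ids = {c.id for c in criteria}
    weighted_ids = sorted({cid for d in definitions.values() for cid in d.weights})

    issues: list[ValidationIssue] = []
    seen: dict[str, int] = {}
    for rec in records:
        if rec.name in seen:
            issues.append(ValidationIssue("error", "duplicate estuary name", estuary=rec.name))
        seen[rec.name] = seen.get(rec.name, 0) + 1

        if rec.region not in REGIONS:
            issues.append(ValidationIssue(
                "warning", f"region {rec.region!r} not in {'/'.join(REGIONS)}",
                estuary=rec.name))

        for cid, s in rec.scores.items():
            if cid not in known_ids:
                issues.append(ValidationIssue(
                    "error", f"score for unregistered criterion id {cid}",
                    estuary=rec.name, criterion=cid))
            if not s.is_missing and s.value not in (0, 1, 2):
                issues.append(ValidationIssue(
                    "error", f"score {s.value!r} outside the 0-2 scale",
                    estuary=rec.name, criterion=cid))
            if not s.is_missing and s.certainty is None:
                issues.append(ValidationIssue(
                    "warning", "scored value has no certainty annotation",
                    estuary=rec.name, criterion=cid))

        core_missing = [cid for cid in (1, 2, 3) if rec.score(cid).is_missing]
        if len(core_missing) == 3:
            issues.append(ValidationIssue(
                "warning",
                "criteria 1-3 (recruitment, extinction risk, mortality) all missing; "
                "record will fail eligibility filtering", estuary=rec.name))
        for cid in weighted_ids:
            if rec.score(cid).is_missing:
                issues.append(ValidationIssue(
                    "warning", "missing value on a criterion weighted by an active "
                    "index; it will score as 0", estuary=rec.name, criterion=cid))
    return issues
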