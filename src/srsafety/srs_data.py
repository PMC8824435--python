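"""Report data model, CSV ingest/export, inclusion filtering and variable coding.

One :class:`AdrReport` is a single spontaneous report: demographics, the
suspect drug, the (single, pre-selected) adverse event term with its
system organ class, onset timing, severity, impact on the primary
disease, and history flags. Reports are exchanged as UTF-8 CSV, one row
per report, with an optional column-name dialect map so arbitrary SRS
export formats can be adapted.

Filtering applies the study's inclusion window (reporting years
2016-2020, causality certain/probable/possible, ATC class L01) and
exclusion rules (missing critical information, implausible age, negative
onset time, duplicates), attributing every exclusion to the first
matching rule in a fixed order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from enum import StrEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class Sex(StrEnum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Causality(StrEnum):
    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    OTHER = "other"


class DrugClass(StrEnum):
    MAB = "mab"
    NON_MAB = "non_mab"


class MabType(StrEnum):
    CHIMERIC = "chimeric"
    HUMANIZED = "humanized"
    FULLY_HUMAN = "fully_human"
    NONE = "none"


class PatentStatus(StrEnum):
    BRANDED = "branded"
    BIOSIMILAR = "biosimilar"
    NONE = "none"


class Severity(StrEnum):
    SERIOUS = "serious"
    NON_SERIOUS = "non_serious"


class Impact(StrEnum):
    NO_EFFECT = "no_effect"
    PROLONG = "prolong"
    WORSE = "worse"
    SEQUELAE = "sequelae"
    DEATH = "death"


class OnsetBin(StrEnum):
    SAME_DAY = "same_day"
    D1_3 = "d1_3"
    D4_7 = "d4_7"
    D8_30 = "d8_30"
    D_GT30 = "d_gt30"


#: Age-group labels; boundary values belong to the younger-labelled group.
AGE_GROUPS: tuple[tuple[int, int, str], ...] = (
    (0, 5, "0-5"),
    (6, 17, "6-17"),
    (18, 34, "18-34"),
    (35, 59, "35-59"),
    (60, 79, "60-79"),
    (80, 10**9, ">=80"),
)

INCLUDED_YEARS = range(2016, 2021)
INCLUDED_ATC = "L01"
MAX_AGE = 120


@dataclass(frozen=True, slots=True)
class AdrReport:
    """A single spontaneous ADR report.

    ``age`` and ``onset_days`` may be ``None`` (missing); ``n_diseases``
    and ``n_medications`` may be ``None`` when the source record omits
    them — missing values are never encoded as sentinel numbers.
    ``onset_days`` is the integer day difference from the start of
    medication, with the day of first administration counted as 0.
    """

    report_id: str
    year: int
    age: int | None
    sex: Sex
    causality: Causality
    drug_name: str
    atc_class: str
    drug_class: DrugClass
    mab_type: MabType
    patent_status: PatentStatus
    adr_term: str
    soc: str
    onset_days: int | None
    severity: Severity
    impact: Impact
    n_diseases: int | None
    n_medications: int | None
    past_adr_history: bool
    outcome_death: bool


#: Canonical CSV column order (also the schema field names).
CSV_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(AdrReport))


class SchemaError(ValueError):
    """A required column is absent or the dialect map is unusable."""


class DomainError(ValueError):
    """An argument falls outside its documented domain."""


def _parse_optional_int(cell: str) -> int | None:
    cell = cell.strip()
    if cell == "":
        return None
    return int(float(cell)) if "." in cell else int(cell)


def _parse_bool(cell: str) -> bool:
    v = cell.strip().lower()
    if v in {"true", "1", "yes", "y"}:
        return True
    if v in {"false", "0", "no", "n", ""}:
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def _coerce_enum(enum_cls, cell: str, fallback):
    """Map a raw label onto an enum; unknown labels go to the fallback."""
    v = cell.strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return enum_cls(v)
    except ValueError:
        if fallback is None:
            raise
        logger.warning("unrecognized %s label %r mapped to %s",
                       enum_cls.__name__, cell, fallback.value)
        return fallback


def parse_reports(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[AdrReport]:
    """Read a report CSV into :class:`AdrReport` records.

    Parameters
    ----------
    path
        CSV file with a header row, one report per row.
    dialect
        Optional map from schema column name to the column name used in
        the file, for adapting third-party export formats. Unmapped
        columns keep their schema names.

    Unknown labels for sex/causality/mab_type/patent_status are mapped
    to their catch-all level with a logged warning; rows whose severity,
    impact, drug class or numeric fields cannot be parsed are skipped
    with a logged row-level error. Missing numeric cells become ``None``.

    Raises
    ------
    SchemaError
        If any required column is absent from the header (the message
        names the column).
    """
    path = Path(path)
    dialect = dict(dialect or {})
    colmap = {name: dialect.get(name, name) for name in CSV_COLUMNS}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for schema_name, file_name in colmap.items():
            if file_name not in header:
                raise SchemaError(
                    f"required column {file_name!r} (schema field "
                    f"{schema_name!r}) missing from {path}"
                )
        reports: list[AdrReport] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                reports.append(_parse_row(row, colmap))
            except (ValueError, KeyError) as exc:
                logger.error("%s:%d skipped unparseable row: %s",
                             path, lineno, exc)
    return reports


def _parse_row(row: Mapping[str, str], colmap: Mapping[str, str]) -> AdrReport:
    def cell(name: str) -> str:
        return (row.get(colmap[name]) or "").strip()

    impact = _coerce_enum(Impact, cell("impact"), None)
    return AdrReport(
        report_id=cell("report_id"),
        year=int(cell("year")),
        age=_parse_optional_int(cell("age")),
        sex=_coerce_enum(Sex, cell("sex"), Sex.UNKNOWN),
        causality=_coerce_enum(Causality, cell("causality"), Causality.OTHER),
        drug_name=cell("drug_name"),
        atc_class=cell("atc_class"),
        drug_class=_coerce_enum(DrugClass, cell("drug_class"), None),
        mab_type=_coerce_enum(MabType, cell("mab_type"), MabType.NONE),
        patent_status=_coerce_enum(PatentStatus, cell("patent_status"),
                                   PatentStatus.NONE),
        adr_term=cell("adr_term"),
        soc=cell("soc"),
        onset_days=_parse_optional_int(cell("onset_days")),
        severity=_coerce_enum(Severity, cell("severity"), None),
        impact=impact,
        n_diseases=_parse_optional_int(cell("n_diseases")),
        n_medications=_parse_optional_int(cell("n_medications")),
        past_adr_history=_parse_bool(cell("past_adr_history")),
        outcome_death=_parse_bool(cell("outcome_death")),
    )


def write_reports(reports: Iterable[AdrReport], path: str | Path) -> None:
    """Write reports to CSV in the canonical schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in reports:
            writer.writerow([
                "" if getattr(r, name) is None
                else str(getattr(r, name)).lower()
                if isinstance(getattr(r, name), bool)
                else getattr(r, name).value
                if hasattr(getattr(r, name), "value")
                else getattr(r, name)
                for name in CSV_COLUMNS
            ])


# --------------------------------------------------------------------------
# Inclusion / exclusion filtering
# --------------------------------------------------------------------------

#: Fixed rule order; each excluded report is attributed to the first match.
FILTER_RULES: tuple[str, ...] = (
    "year", "causality", "atc", "missing-info", "age>120",
    "negative-onset", "duplicate",
)

#: Fields forming the conservative duplicate key.
DUPLICATE_KEY_FIELDS = ("year", "age", "sex", "drug_name", "adr_term",
                        "onset_days")


@dataclass(slots=True)
class FilterReport:
    """Accounting of one filtering pass.

    ``n_input == n_retained + sum(count for _, count in exclusions)``
    always holds, because each report is excluded by exactly its first
    matching rule.
    """

    n_input: int = 0
    n_retained: int = 0
    exclusions: list[tuple[str, int]] = field(default_factory=list)
    log: list[tuple[str, str]] = field(default_factory=list)


def _first_violation(report: AdrReport, seen_keys: set) -> str | None:
    if report.year not in INCLUDED_YEARS:
        return "year"
    if report.causality not in (Causality.CERTAIN, Causality.PROBABLE,
                                Causality.POSSIBLE):
        return "causality"
    if report.atc_class != INCLUDED_ATC:
        return "atc"
    if report.age is None or not report.drug_name or not report.adr_term:
        return "missing-info"
    if report.age > MAX_AGE:
        return "age>120"
    if report.onset_days is not None and report.onset_days < 0:
        return "negative-onset"
    key = tuple(getattr(report, f) for f in DUPLICATE_KEY_FIELDS)
    if key in seen_keys:
        return "duplicate"
    return None


def apply_inclusion_filters(
    reports: Sequence[AdrReport],
) -> tuple[list[AdrReport], FilterReport]:
    """Apply the study inclusion/exclusion rules in a single ordered pass.

    A report is retained iff its reporting year is 2016-2020, its
    causality is certain/probable/possible, the suspect drug is in ATC
    class L01, age/drug name/ADR term are present, age <= 120, any
    recorded onset time is non-negative, and it is not a duplicate (on
    year, age, sex, drug name, ADR term, onset days) of an earlier
    retained report. Filtering never raises on content; it is idempotent
    on its own output.
    """
    retained: list[AdrReport] = []
    fr = FilterReport(n_input=len(reports))
    counts = dict.fromkeys(FILTER_RULES, 0)
    seen: set = set()
    for report in reports:
        rule = _first_violation(report, seen)
        if rule is None:
            retained.append(report)
            seen.add(tuple(getattr(report, f) for f in DUPLICATE_KEY_FIELDS))
        else:
            counts[rule] += 1
            fr.log.append((report.report_id, rule))
    fr.n_retained = len(retained)
    fr.exclusions = [(rule, n) for rule, n in counts.items() if n > 0]
    return retained, fr


# --------------------------------------------------------------------------
# Variable codings
# --------------------------------------------------------------------------

def flag_polypharmacy(n_medications: int) -> bool:
    """True iff the report records use of five or more medications."""
    if n_medications < 1:
        raise DomainError(f"n_medications must be >= 1, got {n_medications}")
    return n_medications >= 5


def dichotomize_impact(impact: Impact | str) -> str:
    """Collapse the five impact levels to ``effect`` / ``no_effect``.

    Prolongation, worsening, sequelae and death of the primary disease
    all count as ``effect``.
    """
    impact = Impact(impact)
    return "no_effect" if impact is Impact.NO_EFFECT else "effect"


def bin_onset(onset_days: int) -> OnsetBin:
    """Map onset day count to the reporting bins.

    0 = same day; 1-3, 4-7, 8-30 days; beyond 30 days. Negative values
    are a domain error (such rows are excluded upstream).
    """
    if onset_days < 0:
        raise DomainError(f"onset_days must be >= 0, got {onset_days}")
    if onset_days == 0:
        return OnsetBin.SAME_DAY
    if onset_days <= 3:
        return OnsetBin.D1_3
    if onset_days <= 7:
        return OnsetBin.D4_7
    if onset_days <= 30:
        return OnsetBin.D8_30
    return OnsetBin.D_GT30


def age_group(age: int) -> str:
    """Age-group label (0-5, 6-17, 18-34, 35-59, 60-79, >=80)."""
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    for lo, hi, label in AGE_GROUPS:
        if lo <= age <= hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover
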