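"""Domain types for individual case safety reports (ICSRs) and MedDRA structure.

An ICSR is one spontaneous report of suspected adverse reactions in one
patient.  Public line-listing exports (EudraVigilance-style) carry one report
per row with demographics, seriousness/outcome flags, suspect drugs and a
sub-delimited list of MedDRA Preferred Terms (PTs).  This module defines the
in-memory record model, the PT->SOC / synonym-merge mapping container, cohort
inclusion criteria, and readers/writers for the delimited dialect.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Region",
    "Seriousness",
    "ReporterQualification",
    "Sex",
    "AgeGroup",
    "SeriousCriterion",
    "ICSRecord",
    "MedDRAMap",
    "CohortCriteria",
    "LineListingDialect",
    "LineListingFormatError",
    "read_line_listing",
    "write_line_listing",
    "normalize_drug_name",
]


class Region(str, Enum):
    EEA = "EEA"
    UK = "UK"
    NON_EEA = "NON_EEA"


class Seriousness(str, Enum):
    SERIOUS = "SERIOUS"
    NON_SERIOUS = "NON_SERIOUS"


class ReporterQualification(str, Enum):
    HEALTHCARE_PROFESSIONAL = "HEALTHCARE_PROFESSIONAL"
    NON_HEALTHCARE_PROFESSIONAL = "NON_HEALTHCARE_PROFESSIONAL"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class AgeGroup(str, Enum):
    """EudraVigilance public age bands (years unless stated)."""

    M_0_1 = "0-1 month"
    M2_Y2 = "2 months-2 years"
    Y3_11 = "3-11 years"
    Y12_17 = "12-17 years"
    Y18_64 = "18-64 years"
    Y65_85 = "65-85 years"
    OVER_85 = ">85 years"
    UNKNOWN = "UNKNOWN"


class SeriousCriterion(str, Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER_MEDICALLY_IMPORTANT = "other_medically_important"


def normalize_drug_name(name: str) -> str:
    """Case-fold and trim a drug name (no brand/INN dictionary mapping)."""
    return name.strip().casefold()


def _normalize_pt(term: str) -> str:
    return " ".join(term.split())


@dataclass(frozen=True)
class ICSRecord:
    """One individual case safety report.

    Invariants enforced at construction: non-empty ``local_report_id`` and
    ``reactions``; PTs unique within a record; a fatal outcome implies a
    serious report with the death criterion set.
    """

    local_report_id: str
    receipt_date: dt.date
    origin_region: Region
    seriousness: Seriousness
    serious_criteria: frozenset[SeriousCriterion]
    outcome_death: bool
    reporter_qualification: ReporterQualification
    sex: Sex
    age_group: AgeGroup
    suspect_drugs: frozenset[str]
    reactions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.local_report_id:
            raise ValueError("local_report_id must be non-empty")
        if not self.reactions:
            raise ValueError(f"record {self.local_report_id}: reactions must be non-empty")
        seen: set[str] = set()
        for pt in self.reactions:
            key = _normalize_pt(pt).casefold()
            if key in seen:
                raise ValueError(
                    f"record {self.local_report_id}: duplicate PT {pt!r} after normalization"
                )
            seen.add(key)
        if self.outcome_death:
            if self.seriousness is not Seriousness.SERIOUS:
                raise ValueError(f"record {self.local_report_id}: fatal outcome must be serious")
            if SeriousCriterion.DEATH not in self.serious_criteria:
                raise ValueError(
                    f"record {self.local_report_id}: fatal outcome requires the death criterion"
                )

    def with_reactions(self, reactions: Sequence[str]) -> "ICSRecord":
        return replace(self, reactions=tuple(reactions))

    def has_reaction(self, term: str) -> bool:
        key = _normalize_pt(term).casefold()
        return any(_normalize_pt(pt).casefold() == key for pt in self.reactions)


@dataclass(frozen=True)
class MedDRAMap:
    """PT -> System Organ Class mapping plus a PT synonym-merge table.

    ``synonym_merge`` collapses PTs with overlapping clinical meaning onto one
    canonical term (e.g. two dissociation-related PTs onto
    ``"Dissociation/dissociative disorder"``).  Merging is idempotent and every
    canonical merge output must be SOC-mapped.  PTs absent from both tables
    pass through unchanged and aggregate under the unmapped bucket.
    """

    pt_to_soc: Mapping[str, str] = field(default_factory=dict)
    synonym_merge: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merge = {self._key(k): _normalize_pt(v) for k, v in self.synonym_merge.items()}
        soc = {self._key(k): v for k, v in self.pt_to_soc.items()}
        object.__setattr__(self, "_merge", merge)
        object.__setattr__(self, "_soc", soc)
        for canonical in merge.values():
            ck = canonical.casefold()
            if ck in merge and merge[ck] != canonical:
                raise ValueError(f"synonym_merge is not idempotent at {canonical!r}")
            if ck not in soc:
                raise ValueError(f"canonical merged term {canonical!r} has no SOC entry")

    @staticmethod
    def _key(term: str) -> str:
        return _normalize_pt(term).casefold()

    def merge_term(self, term: str) -> str:
        """Canonical form of ``term`` (identity for unmapped terms)."""
        return self._merge.get(self._key(term), _normalize_pt(term))  # type: ignore[attr-defined]

    def soc_of(self, term: str) -> str | None:
        """SOC of the canonical form of ``term`` or None when unmapped."""
        return self._soc.get(self._key(self.merge_term(term)))  # type: ignore[attr-defined]

    @property
    def socs(self) -> set[str]:
        return set(self._soc.values())  # type: ignore[attr-defined]

    @classmethod
    def from_csv(cls, soc_path: str | Path, synonym_path: str | Path | None = None) -> "MedDRAMap":
        """Load from two-column CSV files (``pt,soc`` and ``pt,canonical``)."""
        pt_to_soc = _read_two_column_csv(soc_path)
        synonym = _read_two_column_csv(synonym_path) if synonym_path else {}
        return cls(pt_to_soc=pt_to_soc, synonym_merge=synonym)

    def to_csv(self, soc_path: str | Path, synonym_path: str | Path | None = None) -> None:
        _write_two_column_csv(soc_path, ("pt", "soc"), self.pt_to_soc)
        if synonym_path is not None:
            _write_two_column_csv(synonym_path, ("pt", "canonical"), self.synonym_merge)


def _read_two_column_csv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return out
        for row in reader:
            if len(row) < 2:
                raise LineListingFormatError(f"{path}: expected two columns, got {row!r}")
            out[row[0]] = row[1]
    return out


def _write_two_column_csv(path: str | Path, header: tuple[str, str], mapping: Mapping[str, str]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for k, v in mapping.items():
            writer.writerow([k, v])


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion criteria for a study cohort.

    Any criterion set to None/empty is disabled.  The standard serious
    spontaneous-report cohort uses serious reports from healthcare
    professionals originating in the EEA (incl. UK) within a date window,
    restricted to reports naming the drug of interest as suspect.
    """

    require_serious: bool = False
    require_hcp_reporter: bool = False
    allowed_regions: frozenset[Region] | None = None
    date_window: tuple[dt.date, dt.date] | None = None
    drug_of_interest: str | None = None

    def __post_init__(self) -> None:
        if self.date_window is not None:
            start, end = self.date_window
            if start > end:
                raise ValueError(f"date window start {start} is after end {end}")

    def failed_criterion(self, record: ICSRecord) -> str | None:
        """Name of the first criterion ``record`` fails, or None if included."""
        if self.require_serious and record.seriousness is not Seriousness.SERIOUS:
            return "seriousness"
        if (
            self.require_hcp_reporter
            and record.reporter_qualification is not ReporterQualification.HEALTHCARE_PROFESSIONAL
        ):
            return "reporter_qualification"
        if self.allowed_regions is not None and record.origin_region not in self.allowed_regions:
            return "origin_region"
        if self.date_window is not None:
            start, end = self.date_window
            if not (start <= record.receipt_date <= end):
                return "date_window"
        if self.drug_of_interest is not None:
            wanted = normalize_drug_name(self.drug_of_interest)
            if wanted not in {normalize_drug_name(d) for d in record.suspect_drugs}:
                return "drug_of_interest"
        return None

    def accepts(self, record: ICSRecord) -> bool:
        return self.failed_criterion(record) is None


# --------------------------------------------------------------------------
# Line-listing I/O
# --------------------------------------------------------------------------

#: canonical column names of the line-listing dialect
_COLUMNS = (
    "local_report_id",
    "receipt_date",
    "origin_region",
    "seriousness",
    "serious_criteria",
    "outcome_death",
    "reporter_qualification",
    "sex",
    "age_group",
    "suspect_drugs",
    "reactions",
)

_MANDATORY = frozenset(_COLUMNS)


class LineListingFormatError(ValueError):
    """Raised when a line listing violates the expected format."""


@dataclass(frozen=True)
class LineListingDialect:
    """Delimiter/quoting descriptor for the line-listing CSV dialect.

    ``column_map`` translates file header names onto the canonical field
    names, for exports whose headers differ from the defaults.
    """

    delimiter: str = ","
    sub_delimiter: str = ";"
    quotechar: str = '"'
    column_map: Mapping[str, str] = field(default_factory=dict)

    def canonical(self, header: str) -> str:
        return self.column_map.get(header, header)


_SEX_ALIASES = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
}

_AGE_ALIASES = {g.value.casefold(): g for g in AgeGroup} | {
    "0-1 month": AgeGroup.M_0_1,
    "2 months-2 years": AgeGroup.M2_Y2,
    "3-11": AgeGroup.Y3_11,
    "12-17": AgeGroup.Y12_17,
    "18-64": AgeGroup.Y18_64,
    "65-85": AgeGroup.Y65_85,
    ">85": AgeGroup.OVER_85,
}


def _parse_sex(raw: str) -> Sex:
    return _SEX_ALIASES.get(raw.strip().casefold(), Sex.UNKNOWN)


def _parse_age(raw: str) -> AgeGroup:
    return _AGE_ALIASES.get(raw.strip().casefold(), AgeGroup.UNKNOWN)


def _parse_bool(raw: str) -> bool:
    return raw.strip().casefold() in {"true", "1", "yes", "fatal"}


def read_line_listing(
    path: str | Path, dialect: LineListingDialect | None = None
) -> list[ICSRecord]:
    """Parse a delimited line listing into records, preserving file order.

    Unparseable sex/age values map to UNKNOWN.  A missing mandatory column
    raises :class:`LineListingFormatError` naming the column; an empty file
    yields an empty list.
    """
    dialect = dialect or LineListingDialect()
    records: list[ICSRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
        header = next(reader, None)
        if header is None:
            return records
        names = [dialect.canonical(h.strip()) for h in header]
        missing = _MANDATORY - set(names)
        if missing:
            raise LineListingFormatError(
                f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
            )
        index = {name: i for i, name in enumerate(names)}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                records.append(_row_to_record(row, index, dialect))
            except (ValueError, KeyError, IndexError) as exc:
                raise LineListingFormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _row_to_record(row: Sequence[str], index: Mapping[str, int], dialect: LineListingDialect) -> ICSRecord:
    def cell(name: str) -> str:
        return row[index[name]]

    criteria = frozenset(
        SeriousCriterion(c.strip())
        for c in cell("serious_criteria").split(dialect.sub_delimiter)
        if c.strip()
    )
    drugs = frozenset(
        normalize_drug_name(d)
        for d in cell("suspect_drugs").split(dialect.sub_delimiter)
        if d.strip()
    )
    reactions = tuple(
        _normalize_pt(r) for r in cell("reactions").split(dialect.sub_delimiter) if r.strip()
    )
    return ICSRecord(
        local_report_id=cell("local_report_id").strip(),
        receipt_date=dt.date.fromisoformat(cell("receipt_date").strip()),
        origin_region=Region(cell("origin_region").strip()),
        seriousness=Seriousness(cell("seriousness").strip()),
        serious_criteria=criteria,
        outcome_death=_parse_bool(cell("outcome_death")),
        reporter_qualification=ReporterQualification(cell("reporter_qualification").strip()),
        sex=_parse_sex(cell("sex")),
        age_group=_parse_age(cell("age_group")),
        suspect_drugs=drugs,
        reactions=reactions,
    )


def write_line_listing(
    records: Iterable[ICSRecord],
    path: str | Path,
    dialect: LineListingDialect | None = None,
) -> None:
    """Serialize records so that :func:`read_line_listing` round-trips them."""
    dialect = dialect or LineListingDialect()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, quotechar=dialect.quotechar)
        writer.writerow(_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.local_report_id,
                    rec.receipt_date.isoformat(),
                    rec.origin_region.value,
                    rec.seriousness.value,
                    dialect.sub_delimiter.join(sorted(c.value for c in rec.serious_criteria)),
                    "true" if rec.outcome_death else "false",
                    rec.reporter_qualification.value,
                    rec.sex.value,
                    rec.age_group.value,
                    dialect.sub_delimiter.join(sorted(rec.suspect_drugs)),
                    dialect.sub_delimiter.join(rec.reactions),
                ]
            )
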