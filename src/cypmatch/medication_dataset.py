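"""Read, split, clean and aggregate medication-entry tables.

One row of input is one documented drug use in one case (an emergency-
department adverse-drug-reaction case in the motivating dataset).  Rows may
document combination products ("hydrochlorothiazide/ramipril"), which are
split into one entry per component before anything else.  Entries are then
resolved to canonical English names, cleaned against an exclusion rule table
(unspecific names, food supplements), and aggregated into per-drug records
carrying entry counts and distinct-case counts.  The frequent-drug subset —
drugs occurring in at least a given fraction of cases — is what a manual
literature review can realistically cover.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .name_resolution import NameResolution, normalize_raw

DEFAULT_SEPARATORS: tuple[str, ...] = ("/", "+", " comb.")


class TableParseError(ValueError):
    """Input table violates the configured dialect."""


@dataclass(frozen=True)
class MedicationEntry:
    """One documented drug use: case id, raw substance name, optional ATC."""

    case_id: str
    raw_name: str
    atc_code: str | None = None
    source_row: int = 1
    atc_ambiguous: bool = False  # ATC inherited from a combination product

    def __post_init__(self) -> None:
        if not self.raw_name.strip():
            raise ValueError("raw_name must be non-empty")
        if self.source_row < 1:
            raise ValueError("source_row must be >= 1")


@dataclass(frozen=True)
class DrugRecord:
    """A canonical drug aggregated over all its medication entries."""

    canonical_name: str
    atc_codes: frozenset[str] = frozenset()
    entry_count: int = 1
    case_count: int = 1
    case_fraction: float | None = None
    resolved: bool = True

    def __post_init__(self) -> None:
        if self.entry_count < 1 or self.case_count < 1:
            raise ValueError("entry_count and case_count must be >= 1")
        if self.entry_count < self.case_count:
            raise ValueError("entry_count cannot be below case_count")
        if self.case_fraction is not None and not 0.0 <= self.case_fraction <= 1.0:
            raise ValueError("case_fraction must lie in [0, 1]")


@dataclass
class DatasetSummary:
    """Bookkeeping for one preparation run; conservation is checkable from it."""

    n_cases: int
    n_entries_raw: int
    n_entries_after_split: int
    n_names_raw: int
    n_drugs_final: int
    n_unresolved: int = 0
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "n_cases": self.n_cases,
            "n_entries_raw": self.n_entries_raw,
            "n_entries_after_split": self.n_entries_after_split,
            "n_names_raw": self.n_names_raw,
            "n_drugs_final": self.n_drugs_final,
            "n_unresolved": self.n_unresolved,
            "n_excluded_entries": len(self.exclusion_log),
            "exclusion_log": [list(item) for item in self.exclusion_log],
        }
        return json.dumps(payload, indent=2)


@dataclass
class TableDialect:
    """Column/delimiter configuration for a medication-entry table."""

    case_column: str = "case_id"
    name_column: str = "name"
    atc_column: str | None = "atc"
    delimiter: str = ","
    encoding: str = "utf-8"


@dataclass
class ReadResult:
    entries: list[MedicationEntry]
    rejected: list[tuple[int, str]]  # (line number, reason)


def read_medication_table(
    path: str | Path, dialect: TableDialect | None = None
) -> ReadResult:
    """Read a delimited medication table into entries.

    Rows with an empty substance name are rejected and reported with their
    line number rather than silently dropped; missing mandatory columns and
    ragged rows raise :class:`TableParseError`.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[MedicationEntry] = []
    rejected: list[tuple[int, str]] = []
    with path.open(encoding=dialect.encoding, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: empty file")
        required = [dialect.case_column, dialect.name_column]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise TableParseError(f"{path}: missing mandatory column(s) {missing}")
        has_atc = dialect.atc_column is not None and dialect.atc_column in reader.fieldnames
        for row in reader:
            line_no = reader.line_num
            if None in row or any(v is None for v in row.values()):
                raise TableParseError(
                    f"{path}: line {line_no}: field count does not match header "
                    "(malformed delimiter?)"
                )
            name = (row[dialect.name_column] or "").strip()
            if not name:
                rejected.append((line_no, "empty substance name"))
                continue
            atc = (row[dialect.atc_column] or "").strip() if has_atc else ""
            entries.append(
                MedicationEntry(
                    case_id=(row[dialect.case_column] or "").strip(),
                    raw_name=name,
                    atc_code=atc or None,
                    source_row=line_no,
                )
            )
    return ReadResult(entries=entries, rejected=rejected)


def split_combination(
    entry: MedicationEntry,
    separators: Sequence[str] = DEFAULT_SEPARATORS,
) -> list[MedicationEntry]:
    """Split a combination product into one entry per component substance.

    Each component inherits the case id and source row; a combination-level
    ATC code (one code for the whole product) is attached to every component
    and flagged ambiguous, since it does not identify any single substance.
    """
    pattern = "|".join(re.escape(sep) for sep in separators)
    parts = [p.strip() for p in re.split(pattern, entry.raw_name)]
    parts = [p for p in parts if p]
    if not parts:
        raise ValueError(f"row {entry.source_row}: name {entry.raw_name!r} is separator-only")
    if len(parts) == 1:
        return [replace(entry, raw_name=parts[0])]
    return [
        replace(entry, raw_name=part, atc_ambiguous=entry.atc_code is not None)
        for part in parts
    ]


@dataclass
class ExclusionRules:
    """User-editable cleaning rules: unspecific names and supplement ATC groups."""

    names: set[str] = field(default_factory=set)
    atc_prefixes: tuple[str, ...] = ()

    def match(self, canonical_name: str, atc_codes: Iterable[str]) -> str | None:
        """Return the rule label that excludes this drug, or ``None``."""
        if canonical_name in self.names:
            return f"name:{canonical_name}"
        for code in atc_codes:
            for prefix in self.atc_prefixes:
                if code.upper().startswith(prefix.upper()):
                    return f"atc_prefix:{prefix}"
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "ExclusionRules":
        """Load a TSV rule table with columns ``kind`` (name|atc_prefix), ``pattern``."""
        names: set[str] = set()
        prefixes: list[str] = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("kind\t"):
                continue
            kind, _, pattern = line.partition("\t")
            pattern = pattern.strip()
            if kind == "name":
                names.add(pattern.lower())
            elif kind == "atc_prefix":
                prefixes.append(pattern.upper())
            else:
                raise ValueError(f"{path}: unknown exclusion rule kind {kind!r}")
        return cls(names=names, atc_prefixes=tuple(prefixes))


def aggregate_drugs(
    entries: Sequence[MedicationEntry],
    resolutions: Mapping[str, NameResolution],
    *,
    exclusions: ExclusionRules | None = None,
    n_entries_raw: int | None = None,
    n_names_raw: int | None = None,
) -> tuple[list[DrugRecord], DatasetSummary]:
    """Group resolved entries into per-drug records plus a run summary.

    ``resolutions`` maps each entry's raw name to its :class:`NameResolution`;
    unresolved entries are kept (grouped under the normalized raw name,
    flagged unresolved) so downstream classification can report them as
    not assessed rather than losing them.  Conservation holds by
    construction: total entry_count over records = entries in − excluded.
    """
    exclusions = exclusions or ExclusionRules()
    per_drug_entries: dict[str, int] = {}
    per_drug_cases: dict[str, set[str]] = {}
    per_drug_atcs: dict[str, set[str]] = {}
    drug_resolved: dict[str, bool] = {}
    exclusion_log: list[tuple[str, str]] = []
    n_unresolved = 0
    all_cases = {e.case_id for e in entries}

    for entry in entries:
        try:
            resolution = resolutions[entry.raw_name]
        except KeyError as exc:
            raise KeyError(f"no resolution supplied for raw name {entry.raw_name!r}") from exc
        if resolution.resolved:
            canonical = resolution.canonical_name
            resolved = True
        else:
            canonical = normalize_raw(entry.raw_name)
            resolved = False
            n_unresolved += 1
        atcs = set()
        if entry.atc_code and not entry.atc_ambiguous:
            atcs.add(entry.atc_code.upper())
        rule = exclusions.match(canonical, atcs)
        if rule is not None:
            exclusion_log.append((entry.raw_name, rule))
            continue
        per_drug_entries[canonical] = per_drug_entries.get(canonical, 0) + 1
        per_drug_cases.setdefault(canonical, set()).add(entry.case_id)
        per_drug_atcs.setdefault(canonical, set()).update(atcs)
        drug_resolved[canonical] = drug_resolved.get(canonical, True) and resolved

    n_cases = len(all_cases)
    records = [
        DrugRecord(
            canonical_name=name,
            atc_codes=frozenset(per_drug_atcs[name]),
            entry_count=per_drug_entries[name],
            case_count=len(per_drug_cases[name]),
            case_fraction=len(per_drug_cases[name]) / n_cases if n_cases else None,
            resolved=drug_resolved[name],
        )
        for name in per_drug_entries
    ]
    records.sort(key=lambda r: (-r.entry_count, r.canonical_name))
    summary = DatasetSummary(
        n_cases=n_cases,
        n_entries_raw=n_entries_raw if n_entries_raw is not None else len(entries),
        n_entries_after_split=len(entries) - len(exclusion_log),
        n_names_raw=n_names_raw
        if n_names_raw is not None
        else len({e.raw_name for e in entries}),
        n_drugs_final=len(records),
        n_unresolved=n_unresolved,
        exclusion_log=exclusion_log,
    )
    assert sum(r.entry_count for r in records) == summary.n_entries_after_split
    return records, summary


def select_frequent_drugs(
    records: Sequence[DrugRecord], threshold_fraction: float
) -> list[DrugRecord]:
    """Drugs occurring in at least ``threshold_fraction`` of all cases.

    The comparison is on the fraction of *distinct cases* documenting the
    drug, not on entries — repeat documentation within one case does not
    make a drug more frequent.  Result ordered by descending entry count.
    """
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1]")
    for record in records:
        if record.case_fraction is None:
            raise ValueError(
                f"record {record.canonical_name!r} lacks case_fraction "
                "(total case count unknown)"
            )
    selected = [r for r in records if r.case_fraction >= threshold_fraction]
    selected.sort(key=lambda r: (-r.entry_count, r.canonical_name))
    return selected


def write_records_csv(records: Sequence[DrugRecord], path: str | Path) -> None:
    """DrugRecord table as CSV (one row per canonical drug)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["canonical_name", "atc_codes", "entry_count", "case_count", "case_fraction", "resolved"]
        )
        for r in records:
            writer.writerow(
                [
                    r.canonical_name,
                    ";".join(sorted(r.atc_codes)),
                    r.entry_count,
                    r.case_count,
                    "" if r.case_fraction is None else f"{r.case_fraction:.6f}",
                    int(r.resolved),
                ]
            )


def read_records_csv(path: str | Path) -> list[DrugRecord]:
    """Inverse of :func:`write_records_csv`."""
    records = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                DrugRecord(
                    canonical_name=row["canonical_name"],
                    atc_codes=frozenset(filter(None, row["atc_codes"].split(";"))),
                    entry_count=int(row["entry_count"]),
                    case_count=int(row["case_count"]),
                    case_fraction=float(row["case_fraction"]) if row["case_fraction"] else None,
                    resolved=bool(int(row.get("resolved", "1"))),
                )
            )
    return records
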