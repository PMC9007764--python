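"""Event-log data model for multidimensional work-observation studies.

A continuous direct-observation session records every task a clinician
performs as a timestamped interval carrying four dimension labels
(*what* was done, *where*, *how* and with *whom*), plus interruption
linkage: an interruption is itself a recorded task that begins inside
another task's interval.  This module defines the in-memory model
(:class:`TaskRecord`, :class:`SessionRecord`, :class:`ObservationDataset`),
the canonical CSV/JSON serialisations, structural validation, and
dimension-aware filtering via :class:`Selector`.

Timestamps are stored at one-second resolution and every task interval is
half-open ``[start, end)``, so durations are integer seconds and two tasks
that abut (one ends exactly when the next starts) do not overlap.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "WHAT_CATEGORIES",
    "DRUG_SPLIT_CATEGORIES",
    "SUBCATEGORIES",
    "HOW_LABELS",
    "WHO_LABELS",
    "NONE_LABEL",
    "TaskRecord",
    "SessionRecord",
    "ObservationDataset",
    "Selector",
    "ALL",
    "ValidationIssue",
    "ValidationReport",
    "EventLogError",
    "DatasetValidationError",
    "read_event_log",
    "write_event_log",
    "validate_dataset",
    "filter_records",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Task categories of the *what* dimension.
WHAT_CATEGORIES: tuple[str, ...] = (
    "Examination/Treatment",
    "Gather information",
    "Documentation",
    "Professional communication",
    "Social",
    "Unknown",
    "Hygiene",
    "Movement",
    "Outside ED",
)

#: Categories that split into drug-related / non-drug-related subcategories.
DRUG_SPLIT_CATEGORIES: frozenset[str] = frozenset(
    {"Gather information", "Documentation", "Professional communication"}
)

NONE_LABEL = "none"

SUBCATEGORIES: tuple[str, ...] = (
    "drug-related",
    "non-drug-related",
    "professional",
    "non-professional",
    NONE_LABEL,
)

HOW_LABELS: tuple[str, ...] = (
    "Direct",
    "Telephone",
    "On paper",
    "On computer",
    "On smartphone",
    "With Prescription Intermediary",
    "With dictaphone",
    NONE_LABEL,
)

WHO_LABELS: tuple[str, ...] = (
    "Patient",
    "Next of kin",
    "Another physician",
    "Nurse",
    "Pharmacist",
    "Other hospital",
    "General Practitioner",
    "Unknown",
    "Others",
    NONE_LABEL,
)

AFFILIATIONS: tuple[str, ...] = ("Medical", "Surgical")
EXPERIENCE_LEVELS: tuple[str, ...] = ("experienced", "inexperienced")


class EventLogError(Exception):
    """Malformed event-log file (parse failure naming row and field)."""


class DatasetValidationError(Exception):
    """Dataset failed structural validation; carries the full report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(
            "dataset validation failed:\n"
            + "\n".join(f"  - {issue}" for issue in report.issues)
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(kw_only=True)
class TaskRecord:
    """One observed task interval with all four dimension labels.

    ``start``/``end`` are wall-clock timestamps at 1 s resolution and the
    interval is half-open ``[start, end)``.  An interruption (stopping the
    current task to respond to an external stimulus) is itself a
    ``TaskRecord`` with ``is_interruption=True`` linked to the record it
    interrupts, whose interval must contain this record's start.
    """

    record_id: str
    session_id: str
    what: str
    subcategory: str = NONE_LABEL
    where_label: str = NONE_LABEL
    how_label: str = NONE_LABEL
    who_label: str = NONE_LABEL
    start: datetime = None  # type: ignore[assignment]
    end: datetime = None  # type: ignore[assignment]
    is_interruption: bool = False
    interrupts_record_id: Optional[str] = None

    @property
    def duration_seconds(self) -> int:
        return int((self.end - self.start).total_seconds())


@dataclass(kw_only=True)
class SessionRecord:
    """One two-hour (nominal) continuous observation session of a physician."""

    session_id: str
    physician_id: str
    affiliation: str
    experience: str
    session_start: datetime
    session_end: datetime
    n_new_patients: int = 0
    n_followup_patients: int = 0

    @property
    def duration_seconds(self) -> int:
        return int((self.session_end - self.session_start).total_seconds())


@dataclass
class ObservationDataset:
    """Sessions, physicians and task records of one observation study.

    ``meta`` carries non-serialised provenance (e.g. the synthetic
    generator's realised ground truth) and is excluded from equality so that
    file round-trips compare clean.
    """

    sessions: list[SessionRecord] = field(default_factory=list)
    records: list[TaskRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def total_observation_seconds(self) -> int:
        return sum(s.duration_seconds for s in self.sessions)

    @property
    def total_observation_hours(self) -> float:
        return self.total_observation_seconds / 3600.0

    def session_map(self) -> dict[str, SessionRecord]:
        return {s.session_id: s for s in self.sessions}

    def records_by_session(self) -> dict[str, list[TaskRecord]]:
        out: dict[str, list[TaskRecord]] = {s.session_id: [] for s in self.sessions}
        for r in self.records:
            out.setdefault(r.session_id, []).append(r)
        return out

    def record_map(self) -> dict[str, TaskRecord]:
        return {r.record_id: r for r in self.records}


_SET_FIELDS = ("what_in", "subcategory_in", "where_in", "how_in", "who_in")


@dataclass(frozen=True)
class Selector:
    """Conjunctive predicate over task dimensions and physician groups.

    The empty selector matches every record; selectors compose by
    conjunction (``s1 & s2``).  Group fields (affiliation, experience) are
    resolved through the record's session.
    """

    what_in: Optional[frozenset[str]] = None
    subcategory_in: Optional[frozenset[str]] = None
    where_in: Optional[frozenset[str]] = None
    how_in: Optional[frozenset[str]] = None
    who_in: Optional[frozenset[str]] = None
    affiliation: Optional[str] = None
    experience: Optional[str] = None
    include_interruptions: bool = True

    @staticmethod
    def make(
        *,
        what: str | Iterable[str] | None = None,
        subcategory: str | Iterable[str] | None = None,
        where: str | Iterable[str] | None = None,
        how: str | Iterable[str] | None = None,
        who: str | Iterable[str] | None = None,
        affiliation: str | None = None,
        experience: str | None = None,
        include_interruptions: bool = True,
    ) -> "Selector":
        """Convenience constructor accepting single labels or iterables."""

        def to_set(v):
            if v is None:
                return None
            if isinstance(v, str):
                return frozenset({v})
            return frozenset(v)

        return Selector(
            what_in=to_set(what),
            subcategory_in=to_set(subcategory),
            where_in=to_set(where),
            how_in=to_set(how),
            who_in=to_set(who),
            affiliation=affiliation,
            experience=experience,
            include_interruptions=include_interruptions,
        )

    def matches(self, record: TaskRecord, session: SessionRecord) -> bool:
        if not self.include_interruptions and record.is_interruption:
            return False
        if self.what_in is not None and record.what not in self.what_in:
            return False
        if self.subcategory_in is not None and record.subcategory not in self.subcategory_in:
            return False
        if self.where_in is not None and record.where_label not in self.where_in:
            return False
        if self.how_in is not None and record.how_label not in self.how_in:
            return False
        if self.who_in is not None and record.who_label not in self.who_in:
            return False
        if self.affiliation is not None and session.affiliation != self.affiliation:
            return False
        if self.experience is not None and session.experience != self.experience:
            return False
        return True

    def __and__(self, other: "Selector") -> "Selector":
        def meet(a, b):
            if a is None:
                return b
            if b is None:
                return a
            return a & b

        def meet_scalar(a, b, name):
            if a is None:
                return b
            if b is None:
                return a
            if a != b:
                # contradictory scalars: match nothing via empty what set
                raise ValueError(f"contradictory selector field {name!r}: {a} vs {b}")
            return a

        return Selector(
            what_in=meet(self.what_in, other.what_in),
            subcategory_in=meet(self.subcategory_in, other.subcategory_in),
            where_in=meet(self.where_in, other.where_in),
            how_in=meet(self.how_in, other.how_in),
            who_in=meet(self.who_in, other.who_in),
            affiliation=meet_scalar(self.affiliation, other.affiliation, "affiliation"),
            experience=meet_scalar(self.experience, other.experience, "experience"),
            include_interruptions=self.include_interruptions and other.include_interruptions,
        )


#: The universal selector (matches every record; ALL denominator).
ALL = Selector()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    subject_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject_id}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.issues

    def add(self, kind: str, subject_id: str, message: str) -> None:
        self.issues.append(ValidationIssue(kind, subject_id, message))


def validate_dataset(dataset: ObservationDataset) -> ValidationReport:
    """Check every structural invariant; violations are reported, not raised.

    Rules: positive durations; subcategory compatible with the task category
    (the drug-related split exists only for gathering information,
    documentation and professional communication; professional /
    non-professional only for Social); records inside their session window;
    resolvable session and interruption references with the interruption
    starting inside its target's interval; at most two sessions per
    physician.
    """
    report = ValidationReport()
    session_map = dataset.session_map()
    record_map = dataset.record_map()

    per_physician: dict[str, int] = {}
    seen_sessions: set[str] = set()
    for s in dataset.sessions:
        if s.session_id in seen_sessions:
            report.add("session", s.session_id, "duplicate session_id")
        seen_sessions.add(s.session_id)
        if s.session_end <= s.session_start:
            report.add("session", s.session_id, "session duration must be positive")
        if s.affiliation not in AFFILIATIONS:
            report.add("session", s.session_id, f"unknown affiliation {s.affiliation!r}")
        if s.experience not in EXPERIENCE_LEVELS:
            report.add("session", s.session_id, f"unknown experience {s.experience!r}")
        if s.n_new_patients < 0 or s.n_followup_patients < 0:
            report.add("session", s.session_id, "patient counts must be non-negative")
        per_physician[s.physician_id] = per_physician.get(s.physician_id, 0) + 1
    for pid, n in per_physician.items():
        if n > 2:
            report.add("physician", pid, f"{n} sessions recorded; maximum is two")

    seen_records: set[str] = set()
    for r in dataset.records:
        if r.record_id in seen_records:
            report.add("record", r.record_id, "duplicate record_id")
        seen_records.add(r.record_id)
        if r.end <= r.start:
            report.add("record", r.record_id, "end must be after start")
        if r.what not in WHAT_CATEGORIES:
            report.add("record", r.record_id, f"unknown what category {r.what!r}")
        if r.subcategory not in SUBCATEGORIES:
            report.add("record", r.record_id, f"unknown subcategory {r.subcategory!r}")
        elif r.subcategory in ("drug-related", "non-drug-related"):
            if r.what not in DRUG_SPLIT_CATEGORIES:
                report.add(
                    "record",
                    r.record_id,
                    f"subcategory {r.subcategory!r} not permitted for what={r.what!r}",
                )
        elif r.subcategory in ("professional", "non-professional"):
            if r.what != "Social":
                report.add(
                    "record",
                    r.record_id,
                    f"subcategory {r.subcategory!r} only permitted for Social",
                )
        if r.how_label not in HOW_LABELS:
            report.add("record", r.record_id, f"unknown how label {r.how_label!r}")
        if r.who_label not in WHO_LABELS:
            report.add("record", r.record_id, f"unknown who label {r.who_label!r}")
        session = session_map.get(r.session_id)
        if session is None:
            report.add("record", r.record_id, f"unknown session_id {r.session_id!r}")
        else:
            if r.start < session.session_start or r.end > session.session_end:
                report.add(
                    "record", r.record_id, "task interval outside its session window"
                )
        if r.is_interruption:
            target = record_map.get(r.interrupts_record_id or "")
            if target is None:
                report.add(
                    "record",
                    r.record_id,
                    f"dangling interrupts_record_id {r.interrupts_record_id!r}",
                )
            else:
                if target.session_id != r.session_id:
                    report.add(
                        "record", r.record_id, "interruption targets another session"
                    )
                elif not (target.start <= r.start < target.end):
                    report.add(
                        "record",
                        r.record_id,
                        "interruption start outside target task interval",
                    )
        elif r.interrupts_record_id:
            report.add(
                "record",
                r.record_id,
                "interrupts_record_id set but is_interruption is false",
            )
    return report


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_records(dataset: ObservationDataset, selector: Selector) -> ObservationDataset:
    """Restrict records to those matching ``selector``; sessions unchanged."""
    session_map = dataset.session_map()
    kept = [
        r
        for r in dataset.records
        if r.session_id in session_map and selector.matches(r, session_map[r.session_id])
    ]
    return ObservationDataset(sessions=list(dataset.sessions), records=kept)


# ---------------------------------------------------------------------------
# Serialisation: CSV (records + companion sessions file) and JSON
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "record_id",
    "session_id",
    "what",
    "subcategory",
    "where",
    "how",
    "who",
    "start",
    "end",
    "is_interruption",
    "interrupts_record_id",
]
_SESSION_COLUMNS = [
    "session_id",
    "physician_id",
    "affiliation",
    "experience",
    "session_start",
    "session_end",
    "n_new_patients",
    "n_followup_patients",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


def _format_ts(ts: datetime) -> str:
    return ts.strftime(_TS_FORMAT)


def _parse_ts(text: str, where: str) -> datetime:
    try:
        ts = datetime.fromisoformat(text)
    except ValueError as exc:
        raise EventLogError(f"{where}: bad timestamp {text!r}") from exc
    if ts.microsecond:
        raise EventLogError(f"{where}: sub-second timestamp {text!r} not supported")
    return ts


def sessions_path_for(path: str | Path) -> Path:
    """Companion sessions CSV path for a records CSV path.

    ``foo_records.csv`` maps to ``foo_sessions.csv``; any other name gets a
    ``_sessions.csv`` suffix on the stem.
    """
    p = Path(path)
    stem = p.stem
    if stem.endswith("_records"):
        stem = stem[: -len("_records")]
    return p.with_name(f"{stem}_sessions{p.suffix or '.csv'}")


def _record_to_row(r: TaskRecord) -> dict[str, str]:
    return {
        "record_id": r.record_id,
        "session_id": r.session_id,
        "what": r.what,
        "subcategory": "" if r.subcategory == NONE_LABEL else r.subcategory,
        "where": "" if r.where_label == NONE_LABEL else r.where_label,
        "how": "" if r.how_label == NONE_LABEL else r.how_label,
        "who": "" if r.who_label == NONE_LABEL else r.who_label,
        "start": _format_ts(r.start),
        "end": _format_ts(r.end),
        "is_interruption": "true" if r.is_interruption else "false",
        "interrupts_record_id": r.interrupts_record_id or "",
    }


def _row_to_record(row: dict[str, str], where: str) -> TaskRecord:
    missing = [c for c in _RECORD_COLUMNS if c not in row or row[c] is None]
    if missing:
        raise EventLogError(f"{where}: missing fields {missing}")
    flag = row["is_interruption"].strip().lower()
    if flag not in ("true", "false", ""):
        raise EventLogError(f"{where}: field is_interruption: bad boolean {flag!r}")
    return TaskRecord(
        record_id=row["record_id"],
        session_id=row["session_id"],
        what=row["what"],
        subcategory=row["subcategory"] or NONE_LABEL,
        where_label=row["where"] or NONE_LABEL,
        how_label=row["how"] or NONE_LABEL,
        who_label=row["who"] or NONE_LABEL,
        start=_parse_ts(row["start"], f"{where}: field start"),
        end=_parse_ts(row["end"], f"{where}: field end"),
        is_interruption=flag == "true",
        interrupts_record_id=row["interrupts_record_id"] or None,
    )


def _session_to_row(s: SessionRecord) -> dict[str, str]:
    return {
        "session_id": s.session_id,
        "physician_id": s.physician_id,
        "affiliation": s.affiliation,
        "experience": s.experience,
        "session_start": _format_ts(s.session_start),
        "session_end": _format_ts(s.session_end),
        "n_new_patients": str(s.n_new_patients),
        "n_followup_patients": str(s.n_followup_patients),
    }


def _row_to_session(row: dict[str, str], where: str) -> SessionRecord:
    missing = [c for c in _SESSION_COLUMNS if c not in row or row[c] is None]
    if missing:
        raise EventLogError(f"{where}: missing fields {missing}")
    try:
        n_new = int(row["n_new_patients"])
        n_fu = int(row["n_followup_patients"])
    except ValueError as exc:
        raise EventLogError(f"{where}: bad patient count") from exc
    return SessionRecord(
        session_id=row["session_id"],
        physician_id=row["physician_id"],
        affiliation=row["affiliation"],
        experience=row["experience"],
        session_start=_parse_ts(row["session_start"], f"{where}: field session_start"),
        session_end=_parse_ts(row["session_end"], f"{where}: field session_end"),
        n_new_patients=n_new,
        n_followup_patients=n_fu,
    )


def write_event_log(
    dataset: ObservationDataset,
    path: str | Path,
    format: str = "csv",
    sessions_path: str | Path | None = None,
    validate: bool = True,
) -> None:
    """Write a dataset as CSV (records + companion sessions file) or JSON.

    The emitted file(s) re-read to an equal dataset.  ``validate=True``
    raises :class:`DatasetValidationError` for an invalid dataset.
    """
    if validate:
        report = validate_dataset(dataset)
        if not report.is_valid:
            raise DatasetValidationError(report)
    path = Path(path)
    if format == "csv":
        spath = Path(sessions_path) if sessions_path else sessions_path_for(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_RECORD_COLUMNS)
            writer.writeheader()
            for r in dataset.records:
                writer.writerow(_record_to_row(r))
        with open(spath, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_SESSION_COLUMNS)
            writer.writeheader()
            for s in dataset.sessions:
                writer.writerow(_session_to_row(s))
    elif format == "json":
        doc = {
            "sessions": [_session_to_row(s) for s in dataset.sessions],
            "records": [_record_to_row(r) for r in dataset.records],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


def read_event_log(
    path: str | Path,
    format: str = "csv",
    sessions_path: str | Path | None = None,
    validate: bool = True,
) -> ObservationDataset:
    """Read and validate an event log from CSV or JSON.

    For CSV, ``path`` is the records file and the companion sessions file is
    located via :func:`sessions_path_for` unless given explicitly.  Malformed
    rows raise :class:`EventLogError` naming the row and field; a dataset
    violating cross-reference invariants raises
    :class:`DatasetValidationError` listing all offenders.
    """
    path = Path(path)
    if format == "csv":
        spath = Path(sessions_path) if sessions_path else sessions_path_for(path)
        if not path.exists():
            raise EventLogError(f"records file not found: {path}")
        if not spath.exists():
            raise EventLogError(f"sessions file not found: {spath}")
        sessions: list[SessionRecord] = []
        with open(spath, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = set(_SESSION_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise EventLogError(f"{spath.name}: header missing columns {sorted(missing)}")
            for i, row in enumerate(reader, start=2):
                sessions.append(_row_to_session(row, f"{spath.name} row {i}"))
        records: list[TaskRecord] = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = set(_RECORD_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise EventLogError(f"{path.name}: header missing columns {sorted(missing)}")
            for i, row in enumerate(reader, start=2):
                records.append(_row_to_record(row, f"{path.name} row {i}"))
    elif format == "json":
        if not path.exists():
            raise EventLogError(f"file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise EventLogError(f"{path.name}: invalid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "sessions" not in doc or "records" not in doc:
            raise EventLogError(f"{path.name}: expected object with sessions and records")
        sessions = [
            _row_to_session({k: str(v) if v is not None else "" for k, v in row.items()},
                            f"{path.name} sessions[{i}]")
            for i, row in enumerate(doc["sessions"])
        ]
        records = [
            _row_to_record({k: str(v) if v is not None else "" for k, v in row.items()},
                           f"{path.name} records[{i}]")
            for i, row in enumerate(doc["records"])
        ]
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")

    dataset = ObservationDataset(sessions=sessions, records=records)
    if validate:
        report = validate_dataset(dataset)
        if not report.is_valid:
            raise DatasetValidationError(report)
    return dataset
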