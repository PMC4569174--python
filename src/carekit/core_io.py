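"""Domain record types and delimited-text table I/O.

Every pipeline stage exchanges plain CSV tables (UTF-8, header row, empty
field = missing value).  All dates are integer day offsets from a
configurable epoch; ISO-8601 calendar dates in input files are converted on
read when an epoch is supplied.  Group-membership intervals are half-open
``[start_day, end_day)`` so day counts are plain interval intersections.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Individual",
    "GroupMembership",
    "AgonisticEvent",
    "AffiliationEvent",
    "ProtocolRecord",
    "MorphoRecord",
    "read_table",
    "write_table",
    "records_to_frame",
    "frame_to_records",
]


class SchemaError(ValueError):
    """Raised when a table's header does not match the expected schema."""


class ValidationError(ValueError):
    """Raised when a record violates a type invariant.

    ``row`` is the 1-based data-row number when the record came from a file.
    """

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


FEMALE = "female"
MALE = "male"


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str
    birth_day: int
    death_day: Optional[int] = None
    mother_id: Optional[str] = None
    sire_id: Optional[str] = None
    cohort: Optional[str] = None
    natal_group: Optional[str] = None

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.death_day is not None and not self.birth_day < self.death_day:
            raise ValidationError(
                f"{self.id}: birth_day {self.birth_day} must precede death_day {self.death_day}"
            )
        if self.mother_id == self.id:
            raise ValidationError(f"{self.id}: mother_id equals own id")
        if self.sire_id == self.id:
            raise ValidationError(f"{self.id}: sire_id equals own id")

    def alive_on(self, day: int) -> bool:
        return self.birth_day <= day and (self.death_day is None or day < self.death_day)


@dataclass(frozen=True)
class GroupMembership:
    id: str
    group: str
    start_day: int
    end_day: int

    def __post_init__(self):
        if not self.start_day < self.end_day:
            raise ValidationError(
                f"{self.id}: membership interval [{self.start_day}, {self.end_day}) is empty"
            )


@dataclass(frozen=True)
class AgonisticEvent:
    day: int
    winner_id: str
    loser_id: str

    def __post_init__(self):
        if self.winner_id == self.loser_id:
            raise ValidationError(f"winner_id == loser_id ({self.winner_id!r})")


@dataclass(frozen=True)
class AffiliationEvent:
    day: int
    protocol_id: str
    focal_id: str
    partner_id: str

    def __post_init__(self):
        if self.focal_id == self.partner_id:
            raise ValidationError(f"focal_id == partner_id ({self.focal_id!r})")


@dataclass(frozen=True)
class ProtocolRecord:
    protocol_id: str
    focal_id: str
    day: int
    duration_min: float = 20.0

    def __post_init__(self):
        if not self.duration_min > 0:
            raise ValidationError(f"{self.protocol_id}: duration_min must be > 0")


@dataclass(frozen=True)
class MorphoRecord:
    id: str
    day: int
    body_mass_kg: Optional[float] = None
    crl_cm: Optional[float] = None
    testis_len_mm: Optional[float] = None
    testis_wid_mm: Optional[float] = None

    def __post_init__(self):
        vals = (self.body_mass_kg, self.crl_cm, self.testis_len_mm, self.testis_wid_mm)
        if all(v is None for v in vals):
            raise ValidationError(f"{self.id}: no measurement present")
        for v in vals:
            if v is not None and not v > 0:
                raise ValidationError(f"{self.id}: non-positive measurement {v}")


# (name, converter, required) per record type; converters run on non-empty strings
_DAY = "day"
_SCHEMAS = {
    Individual: (
        ("id", str, True),
        ("sex", str, True),
        ("birth_day", _DAY, True),
        ("death_day", _DAY, False),
        ("mother_id", str, False),
        ("sire_id", str, False),
        ("cohort", str, False),
        ("natal_group", str, False),
    ),
    GroupMembership: (
        ("id", str, True),
        ("group", str, True),
        ("start_day", _DAY, True),
        ("end_day", _DAY, True),
    ),
    AgonisticEvent: (
        ("day", _DAY, True),
        ("winner_id", str, True),
        ("loser_id", str, True),
    ),
    AffiliationEvent: (
        ("day", _DAY, True),
        ("protocol_id", str, True),
        ("focal_id", str, True),
        ("partner_id", str, True),
    ),
    ProtocolRecord: (
        ("protocol_id", str, True),
        ("focal_id", str, True),
        ("day", _DAY, True),
        ("duration_min", float, False),
    ),
    MorphoRecord: (
        ("id", str, True),
        ("day", _DAY, True),
        ("body_mass_kg", float, False),
        ("crl_cm", float, False),
        ("testis_len_mm", float, False),
        ("testis_wid_mm", float, False),
    ),
}

RECORD_TYPES = tuple(_SCHEMAS)


def _parse_day(value: str, epoch: Optional[_dt.date]) -> int:
    try:
        return int(value)
    except ValueError:
        pass
    try:
        date = _dt.date.fromisoformat(value)
    except ValueError:
        raise ValidationError(f"cannot parse day value {value!r}") from None
    if epoch is None:
        raise ValidationError(
            f"calendar date {value!r} in input but no epoch configured"
        )
    return (date - epoch).days


def _collection_checks(record_type, records: Sequence) -> None:
    if record_type is ProtocolRecord:
        seen = set()
        for i, r in enumerate(records, start=1):
            key = (r.focal_id, r.day)
            if key in seen:
                raise ValidationError(
                    f"more than one protocol for focal {r.focal_id} on day {r.day}", row=i
                )
            seen.add(key)
    elif record_type is GroupMembership:
        by_id: dict[str, list[GroupMembership]] = {}
        for r in records:
            by_id.setdefault(r.id, []).append(r)
        for rid, rows in by_id.items():
            rows = sorted(rows, key=lambda r: r.start_day)
            for a, b in zip(rows, rows[1:]):
                if b.start_day < a.end_day:
                    raise ValidationError(
                        f"overlapping membership intervals for id {rid!r}: "
                        f"[{a.start_day},{a.end_day}) and [{b.start_day},{b.end_day})"
                    )


def read_table(path, record_type, epoch: Optional[_dt.date] = None) -> list:
    """Read a CSV table into a list of validated records of ``record_type``.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (carrying the 1-based data-row number) if a row
    violates a type invariant.  Row order is preserved.
    """
    if record_type not in _SCHEMAS:
        raise TypeError(f"unsupported record type {record_type!r}")
    schema = _SCHEMAS[record_type]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for name, _, required in schema:
        if name not in df.columns and required:
            raise SchemaError(f"{path}: missing required column {name!r}")
    records = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = raw._asdict()
        kwargs = {}
        for name, conv, required in schema:
            value = row.get(name, "")
            if value == "":
                if required:
                    raise ValidationError(f"missing value for {name!r}", row=i)
                continue
            try:
                kwargs[name] = _parse_day(value, epoch) if conv is _DAY else conv(value)
            except ValidationError as exc:
                raise ValidationError(str(exc), row=i) from None
            except ValueError:
                raise ValidationError(f"bad value {value!r} for {name!r}", row=i) from None
        try:
            records.append(record_type(**kwargs))
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i) from None
    _collection_checks(record_type, records)
    return records


def write_table(records: Iterable, path) -> None:
    """Write records (all of one type) as CSV; exact inverse of read_table."""
    records = list(records)
    if records:
        record_type = type(records[0])
        if any(type(r) is not record_type for r in records):
            raise TypeError("all records must be of one type")
    else:
        raise TypeError("cannot infer schema from an empty collection; "
                        "use write_empty_table")
    _write(records, type(records[0]), path)


def write_empty_table(record_type, path) -> None:
    """Write a header-only table for ``record_type``."""
    _write([], record_type, path)


def _write(records: Sequence, record_type, path) -> None:
    if record_type not in _SCHEMAS:
        raise TypeError(f"unsupported record type {record_type!r}")
    names = [name for name, _, _ in _SCHEMAS[record_type]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(names) + "\n")
        for r in records:
            values = []
            for name in names:
                v = getattr(r, name)
                values.append("" if v is None else str(v))
            fh.write(",".join(values) + "\n")


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert a homogeneous record list into a DataFrame (None -> NaN)."""
    if not records:
        raise TypeError("cannot infer schema from an empty collection")
    names = [f.name for f in dataclasses.fields(records[0])]
    return pd.DataFrame(
        [[getattr(r, n) for n in names] for r in records], columns=names
    )


def frame_to_records(df: pd.DataFrame, record_type) -> list:
    """Inverse of :func:`records_to_frame` with validation."""
    schema = _SCHEMAS[record_type]
    out = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = raw._asdict()
        kwargs = {}
        for name, conv, required in schema:
            value = row.get(name)
            if value is None or (isinstance(value, float) and pd.isna(value)):
                if required:
                    raise ValidationError(f"missing value for {name!r}", row=i)
                continue
            kwargs[name] = int(value) if conv is _DAY else (
                value if conv is str else conv(value)
            )
        try:
            out.append(record_type(**kwargs))
        except ValidationError as exc:
            raise ValidationError(str(exc), row=i) from None
    _collection_checks(record_type, out)
    return out
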