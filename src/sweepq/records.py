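"""In-memory model of the parameter database.

The database is a flat table: a header of attribute names and one row per
job.  Every cell is a string; the empty string in the ``status`` column
means the job is pending.  Five attribute names are reserved (and matched
case-sensitively): ``id``, ``status``, ``start-time``, ``end-time`` and
``comment``.  Any other attribute carries a simulation parameter; a name
with a leading ``/`` is an XML element path that the settings injector
knows how to write into a settings file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

ID = "id"
STATUS = "status"
START_TIME = "start-time"
END_TIME = "end-time"
COMMENT = "comment"

#: Attribute names with fixed meaning; everything else is a parameter.
RESERVED_ATTRIBUTES = (ID, STATUS, START_TIME, END_TIME, COMMENT)

#: Terminal status values.  Empty string = pending; any other non-terminal
#: value is a free-form label for the task currently executing.
STATUS_SUCCESSFUL = "successful"
STATUS_FAILED = "failed"
STATUS_IN_PROGRESS = "in progress"

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"


def is_pending(status: str) -> bool:
    return status == ""


def is_finished(status: str) -> bool:
    return status in (STATUS_SUCCESSFUL, STATUS_FAILED)


@dataclass
class JobRecord:
    """One row of the parameter table, keyed by attribute name.

    ``cells`` preserves the header order of the table the record came
    from.  Convenience accessors expose the reserved attributes; ``params``
    returns only the non-reserved (parameter) cells.
    """

    cells: dict[str, str]

    def __post_init__(self) -> None:
        if ID not in self.cells or not self.cells[ID]:
            raise SchemaError("job record must carry a non-empty 'id'")
        if STATUS not in self.cells:
            raise SchemaError("job record must carry a 'status' attribute")

    @property
    def id(self) -> str:
        return self.cells[ID]

    @property
    def status(self) -> str:
        return self.cells[STATUS]

    @property
    def start_time(self) -> str:
        return self.cells.get(START_TIME, "")

    @property
    def end_time(self) -> str:
        return self.cells.get(END_TIME, "")

    @property
    def comment(self) -> str:
        return self.cells.get(COMMENT, "")

    @property
    def params(self) -> dict[str, str]:
        return {k: v for k, v in self.cells.items() if k not in RESERVED_ATTRIBUTES}

    def replace(self, **updates: str) -> "JobRecord":
        """Return a copy with the given attribute cells replaced."""
        cells = dict(self.cells)
        for key, value in updates.items():
            cells[key] = value
        return JobRecord(cells)


@dataclass
class ParameterTable:
    """Ordered header plus ordered rows; the full database content."""

    header: list[str]
    rows: list[JobRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_header(self.header)
        seen: set[str] = set()
        for row in self.rows:
            if list(row.cells.keys()) != self.header:
                raise SchemaError(
                    f"row {row.cells.get(ID, '?')!r} does not match header {self.header}"
                )
            if row.id in seen:
                raise SchemaError(f"duplicate job id {row.id!r}")
            seen.add(row.id)

    def job_ids(self) -> list[str]:
        return [row.id for row in self.rows]

    def find(self, job_id: str) -> JobRecord | None:
        for row in self.rows:
            if row.id == job_id:
                return row
        return None

    def copy(self) -> "ParameterTable":
        return ParameterTable(
            list(self.header), [JobRecord(dict(r.cells)) for r in self.rows]
        )


def validate_header(header: list[str]) -> None:
    if ID not in header or STATUS not in header:
        raise SchemaError(
            f"header must contain 'id' and 'status' columns, got {header}"
        )
    if len(set(header)) != len(header):
        raise SchemaError(f"duplicate attribute names in header {header}")
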