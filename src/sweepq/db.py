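"""Database backends for the parameter table.

Workers coordinate exclusively through this table — there is no job
server.  Two reference backends are provided:

* :class:`DelimitedFileDatabase` — a delimited text file (CSV by default)
  on a shared filesystem.  Writes rewrite the whole file to a temporary
  path and rename it into place under an exclusive advisory lock, so
  concurrent local processes see atomic transitions and
  :meth:`~Database.claim_if_pending` is race-free.
* :class:`InMemorySpreadsheet` — an in-memory stand-in for a remote
  spreadsheet service, serializing claims through a compare-and-swap
  contract.  It is the deterministic concurrency harness for tests; a
  live spreadsheet adapter plugs into the same interface.

All cell values are strings and round-trip verbatim.
"""

from __future__ import annotations

import abc
import csv
import os
import threading
import time
from pathlib import Path
from typing import Callable

from .errors import (
    BackendUnavailableError,
    ContentionError,
    NotFoundError,
    SchemaError,
)
from .records import JobRecord, ParameterTable, validate_header

try:  # POSIX advisory locks; fallback below keeps imports working elsewhere
    import fcntl
except ImportError:  # pragma: no cover
    fcntl = None  # type: ignore[assignment]


class Database(abc.ABC):
    """Adapter contract every backend implements.

    Remote spreadsheet services (the distributed mode) implement this same
    surface; the parameter manager and pipeline are backend-agnostic.
    """

    @abc.abstractmethod
    def get_table(self) -> ParameterTable:
        """Return a faithful snapshot of the whole table."""

    @abc.abstractmethod
    def get_attributes(self) -> list[str]:
        """Return the header, in stored order."""

    @abc.abstractmethod
    def update_row(self, job_id: str, record: JobRecord) -> bool:
        """Replace the row with the given id; every other row untouched."""

    @abc.abstractmethod
    def update_cell(self, job_id: str, attribute: str, value: str) -> bool:
        """Set exactly one cell."""

    @abc.abstractmethod
    def claim_if_pending(self, job_id: str, claim_label: str) -> bool:
        """Atomically set status to ``claim_label`` iff it is still empty.

        Returns True on a successful claim, False if some other worker got
        there first (or the job was never pending).  This is the primitive
        that guarantees a job is not run twice.
        """

    def get_row(self, job_id: str) -> JobRecord:
        row = self.get_table().find(job_id)
        if row is None:
            raise NotFoundError(f"no job with id {job_id!r}")
        return row


class DelimitedFileDatabase(Database):
    """Parameter table stored as a delimited text file with a header row.

    Parameters
    ----------
    path:
        Location of the file.  It must exist and its header must contain
        ``id`` and ``status``; duplicate ids are a hard error (silently
        proceeding would corrupt claim semantics).
    delimiter:
        Field separator, comma by default.
    lock_timeout:
        Seconds to wait for the advisory lock before raising
        :class:`ContentionError`.
    """

    def __init__(self, path: str | os.PathLike, delimiter: str = ",",
                 lock_timeout: float = 10.0) -> None:
        self.path = Path(path)
        self.delimiter = delimiter
        self.lock_timeout = lock_timeout
        self._lock_path = self.path.with_name(self.path.name + ".lock")
        # opening must not modify the file: validate via a plain read
        self._read()

    # -- low-level file handling ------------------------------------------

    def _read(self) -> ParameterTable:
        if not self.path.exists():
            raise BackendUnavailableError(f"database file {self.path} does not exist")
        with open(self.path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter=self.delimiter)
            try:
                header = next(reader)
            except StopIteration:
                raise SchemaError(f"{self.path} is empty (no header row)") from None
            validate_header(header)
            rows = []
            for lineno, values in enumerate(reader, start=2):
                if len(values) != len(header):
                    raise SchemaError(
                        f"{self.path}:{lineno}: expected {len(header)} fields, "
                        f"got {len(values)}"
                    )
                rows.append(JobRecord(dict(zip(header, values))))
        return ParameterTable(header, rows)  # re-validates id uniqueness

    def _write(self, table: ParameterTable) -> None:
        tmp = self.path.with_name(self.path.name + ".tmp")
        with open(tmp, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=self.delimiter)
            writer.writerow(table.header)
            for row in table.rows:
                writer.writerow([row.cells[a] for a in table.header])
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, self.path)

    def _locked(self):
        return _FileLock(self._lock_path, self.lock_timeout)

    # -- adapter contract --------------------------------------------------

    def get_table(self) -> ParameterTable:
        return self._read()

    def get_attributes(self) -> list[str]:
        return self._read().header

    def update_row(self, job_id: str, record: JobRecord) -> bool:
        with self._locked():
            table = self._read()
            if list(record.cells.keys()) != table.header:
                raise SchemaError(
                    f"record attributes {list(record.cells)} do not match "
                    f"header {table.header}"
                )
            for i, row in enumerate(table.rows):
                if row.id == job_id:
                    table.rows[i] = record
                    self._write(table)
                    return True
            raise NotFoundError(f"no job with id {job_id!r}")

    def update_cell(self, job_id: str, attribute: str, value: str) -> bool:
        with self._locked():
            table = self._read()
            if attribute not in table.header:
                raise NotFoundError(f"no attribute {attribute!r}")
            for row in table.rows:
                if row.id == job_id:
                    row.cells[attribute] = value
                    self._write(table)
                    return True
            raise NotFoundError(f"no job with id {job_id!r}")

    def claim_if_pending(self, job_id: str, claim_label: str) -> bool:
        with self._locked():
            table = self._read()
            row = table.find(job_id)
            if row is None:
                raise NotFoundError(f"no job with id {job_id!r}")
            if row.status != "":
                return False
            row.cells["status"] = claim_label
            self._write(table)
            return True


class _FileLock:
    """Exclusive advisory lock on a sidecar file (flock with O_EXCL fallback)."""

    def __init__(self, path: Path, timeout: float) -> None:
        self.path = path
        self.timeout = timeout
        self._fd: int | None = None

    def __enter__(self) -> "_FileLock":
        deadline = time.monotonic() + self.timeout
        if fcntl is not None:
            self._fd = os.open(self.path, os.O_CREAT | os.O_RDWR)
            while True:
                try:
                    fcntl.flock(self._fd, fcntl.LOCK_EX | fcntl.LOCK_NB)
                    return self
                except OSError:
                    if time.monotonic() > deadline:
                        os.close(self._fd)
                        self._fd = None
                        raise ContentionError(
                            f"could not lock {self.path} within {self.timeout}s"
                        ) from None
                    time.sleep(0.005)
        while True:  # pragma: no cover - non-POSIX fallback
            try:
                self._fd = os.open(self.path, os.O_CREAT | os.O_EXCL | os.O_RDWR)
                return self
            except FileExistsError:
                if time.monotonic() > deadline:
                    raise ContentionError(
                        f"could not lock {self.path} within {self.timeout}s"
                    ) from None
                time.sleep(0.005)

    def __exit__(self, *exc) -> None:
        if self._fd is not None:
            if fcntl is not None:
                fcntl.flock(self._fd, fcntl.LOCK_UN)
                os.close(self._fd)
            else:  # pragma: no cover
                os.close(self._fd)
                self.path.unlink(missing_ok=True)
            self._fd = None


class InMemorySpreadsheet(Database):
    """In-memory mock of a remote spreadsheet backend.

    Claims go through a compare-and-swap: the status is re-checked under
    an internal mutex immediately before the write, so a claim succeeds
    for at most one caller no matter how reads and writes interleave.
    ``interleave_hook`` is called between the optimistic read and the CAS
    and lets tests inject adversarial schedules (sleeps, thread yields,
    competing writes).
    """

    def __init__(self, table: ParameterTable,
                 interleave_hook: Callable[[], None] | None = None) -> None:
        self._table = table.copy()
        self._mutex = threading.Lock()
        self.interleave_hook = interleave_hook

    def get_table(self) -> ParameterTable:
        with self._mutex:
            return self._table.copy()

    def get_attributes(self) -> list[str]:
        with self._mutex:
            return list(self._table.header)

    def update_row(self, job_id: str, record: JobRecord) -> bool:
        with self._mutex:
            if list(record.cells.keys()) != self._table.header:
                raise SchemaError("record attributes do not match header")
            for i, row in enumerate(self._table.rows):
                if row.id == job_id:
                    self._table.rows[i] = JobRecord(dict(record.cells))
                    return True
            raise NotFoundError(f"no job with id {job_id!r}")

    def update_cell(self, job_id: str, attribute: str, value: str) -> bool:
        with self._mutex:
            if attribute not in self._table.header:
                raise NotFoundError(f"no attribute {attribute!r}")
            for row in self._table.rows:
                if row.id == job_id:
                    row.cells[attribute] = value
                    return True
            raise NotFoundError(f"no job with id {job_id!r}")

    def claim_if_pending(self, job_id: str, claim_label: str) -> bool:
        # optimistic read outside the mutex, as a remote client would do
        row = self.get_table().find(job_id)
        if row is None:
            raise NotFoundError(f"no job with id {job_id!r}")
        if row.status != "":
            return False
        if self.interleave_hook is not None:
            self.interleave_hook()
        # compare-and-swap: re-check under the mutex
        with self._mutex:
            live = self._table.find(job_id)
            assert live is not None
            if live.status != "":
                return False
            live.cells["status"] = claim_label
            return True


def open_database(source: str | os.PathLike | ParameterTable, *,
                  backend: str = "delimited", delimiter: str = ",") -> Database:
    """Open a parameter database.

    ``backend="delimited"`` opens a delimited text file at ``source``;
    ``backend="memory"`` wraps a :class:`ParameterTable` in the in-memory
    spreadsheet mock.  Opening never modifies stored rows.
    """
    if backend == "delimited":
        return DelimitedFileDatabase(source, delimiter=delimiter)
    if backend == "memory":
        if not isinstance(source, ParameterTable):
            raise TypeError("memory backend requires a ParameterTable")
        return InMemorySpreadsheet(source)
    raise ValueError(f"unknown backend {backend!r}")
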