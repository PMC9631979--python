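"""Job lifecycle management: claim, progress, completion, resume.

A :class:`ParameterManager` sits between a user pipeline and a
:class:`~sweepq.db.Database`.  It hands out pending jobs one at a time
(first row in table order with an empty status), marks them "in
progress", stamps timestamps, records success or failure, honors the
session's run limit, and — via the ``last-test`` key of the run config —
re-yields an interrupted job after a crash instead of abandoning it.
"""

from __future__ import annotations

import logging
from datetime import datetime
from typing import Callable

from .config import LAST_TEST, Config
from .db import Database
from .errors import NotFoundError
from .records import (
    COMMENT,
    END_TIME,
    START_TIME,
    STATUS_FAILED,
    STATUS_IN_PROGRESS,
    STATUS_SUCCESSFUL,
    TIMESTAMP_FORMAT,
    JobRecord,
    is_finished,
)

log = logging.getLogger(__name__)


def _now() -> str:
    return datetime.now().strftime(TIMESTAMP_FORMAT)


class ParameterManager:
    """Claim/status lifecycle over a parameter database.

    Parameters
    ----------
    db:
        Any database backend.
    config:
        Optional run config.  When given, ``num-of-runs`` caps how many
        jobs this session may start (-1 = unlimited) and ``last-test``
        persists the current job id for crash-resume.
    predicate:
        Optional filter on candidate rows; jobs it rejects are skipped
        (e.g. jobs requiring compute this worker lacks).  Default accepts
        every row.
    claim_retries:
        How many times to re-scan the table when every visible pending
        row is stolen by another worker between read and claim.
    """

    claim_label = STATUS_IN_PROGRESS

    def __init__(self, db: Database, config: Config | None = None,
                 predicate: Callable[[JobRecord], bool] | None = None,
                 claim_retries: int = 5) -> None:
        self.db = db
        self.config = config
        self.predicate = predicate or (lambda row: True)
        self.claim_retries = claim_retries
        self.num_of_runs = config.num_of_runs if config is not None else -1
        self.jobs_started = 0

    # -- claiming ----------------------------------------------------------

    def next_parameters(self) -> JobRecord | None:
        """Claim and return the next job, or None when there is no work.

        Resume takes precedence: if the config's ``last-test`` names a job
        that is neither successful nor failed, that job is returned again
        without consuming the run limit — it was already started by a
        previous session that crashed or was stopped.  Otherwise the first
        pending row (empty status) in table order is claimed atomically.
        """
        resumed = self._resume_candidate()
        if resumed is not None:
            log.info("resuming interrupted job %s", resumed.id)
            return resumed
        if 0 <= self.num_of_runs <= self.jobs_started:
            log.info("run limit of %d jobs reached", self.num_of_runs)
            return None
        for _ in range(self.claim_retries + 1):
            candidates = [
                row for row in self.db.get_table().rows
                if row.status == "" and self.predicate(row)
            ]
            if not candidates:
                return None
            for row in candidates:
                if self.db.claim_if_pending(row.id, self.claim_label):
                    return self._start(row.id)
            # every candidate was claimed by someone else; re-scan
        return None

    def _resume_candidate(self) -> JobRecord | None:
        if self.config is None:
            return None
        last = self.config.last_test
        if not last:
            return None
        try:
            row = self.db.get_row(last)
        except NotFoundError:
            return None
        if is_finished(row.status):
            return None
        return row

    def _start(self, job_id: str) -> JobRecord:
        self.jobs_started += 1
        if START_TIME in self.db.get_attributes():
            self.db.update_cell(job_id, START_TIME, _now())
        if self.config is not None:
            self.config.set_value(LAST_TEST, job_id)
        log.info("claimed job %s", job_id)
        return self.db.get_row(job_id)

    # -- status updates ----------------------------------------------------

    def update_status(self, job_id: str, status: str) -> JobRecord:
        """Set a job's status to a free-form task label.

        Any job may be targeted, not only the one this worker claimed:
        coordination is trust-based, exactly as on a shared spreadsheet.
        """
        self.db.update_cell(job_id, "status", status)
        return self.db.get_row(job_id)

    def successful(self, job_id: str) -> JobRecord:
        """Mark a job complete: status "successful", end-time stamped."""
        self.db.update_cell(job_id, "status", STATUS_SUCCESSFUL)
        if END_TIME in self.db.get_attributes():
            self.db.update_cell(job_id, END_TIME, _now())
        self._clear_last_test(job_id)
        log.info("job %s successful", job_id)
        return self.db.get_row(job_id)

    def failed(self, job_id: str, reason: str = "") -> JobRecord:
        """Mark a job failed; a non-empty reason is appended to its comment."""
        self.db.update_cell(job_id, "status", STATUS_FAILED)
        attributes = self.db.get_attributes()
        if END_TIME in attributes:
            self.db.update_cell(job_id, END_TIME, _now())
        if reason and COMMENT in attributes:
            row = self.db.get_row(job_id)
            comment = f"{row.comment}; {reason}" if row.comment else reason
            self.db.update_cell(job_id, COMMENT, comment)
        self._clear_last_test(job_id)
        log.info("job %s failed: %s", job_id, reason or "(no reason given)")
        return self.db.get_row(job_id)

    def _clear_last_test(self, job_id: str) -> None:
        if self.config is not None and self.config.last_test == job_id:
            self.config.set_value(LAST_TEST, None)
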