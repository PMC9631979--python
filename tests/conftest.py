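import random

import pytest

from sweepq import DelimitedFileDatabase, JobRecord, ParameterTable, sample_db
from sweepq.records import RESERVED_ATTRIBUTES

STANDARD_HEADER = list(RESERVED_ATTRIBUTES)


def make_table(n_jobs: int, statuses: list[str] | None = None,
               extra: dict[str, str] | None = None) -> ParameterTable:
    """Build a small in-memory table with ids job000, job001, ..."""
    extra = extra or {}
    header = STANDARD_HEADER + list(extra)
    rows = []
    for i in range(n_jobs):
        status = statuses[i] if statuses else ""
        cells = {"id": f"job{i:03d}", "status": status, "start-time": "",
                 "end-time": "", "comment": "", **extra}
        rows.append(JobRecord(cells))
    return ParameterTable(header, rows)


def make_random_table(rng: random.Random, n_jobs: int) -> ParameterTable:
    """Table with a random mix of pending/terminal/in-flight statuses."""
    pool = ["", "", "successful", "failed", "in progress", "postprocessing"]
    statuses = [rng.choice(pool) for _ in range(n_jobs)]
    return make_table(n_jobs, statuses=statuses,
                      extra={"/user_parameters/x": "1.0"})


@pytest.fixture
def sample_csv(tmp_path):
    """The bundled three-job example database on disk."""
    return sample_db(tmp_path / "parameters.csv")


@pytest.fixture
def sample_database(sample_csv):
    return DelimitedFileDatabase(sample_csv)
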