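"""Database backends: schema validation, locality of writes, claim atomicity."""

import csv
import hashlib
import random
import threading

import pytest

from sweepq import (
    BackendUnavailableError,
    DelimitedFileDatabase,
    InMemorySpreadsheet,
    JobRecord,
    NotFoundError,
    SchemaError,
    open_database,
)
from conftest import make_table


def raw_rows(path):
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.reader(fh))


class TestOpen:
    def test_sample_database_shape(self, sample_database):
        table = sample_database.get_table()
        assert len(table.header) == 7
        assert table.job_ids() == ["default", "attached", "unattached"]
        assert all(row.status == "" for row in table.rows)

    def test_header_only_file_has_no_rows(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,status\n")
        db = DelimitedFileDatabase(path)
        assert db.get_table().rows == []

    def test_duplicate_id_is_schema_violation(self, tmp_path, sample_csv):
        rows = raw_rows(sample_csv)
        rows.append(rows[1])  # duplicate the "default" job
        path = tmp_path / "dup.csv"
        with open(path, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        with pytest.raises(SchemaError, match="duplicate"):
            DelimitedFileDatabase(path)

    def test_missing_file_and_bad_header(self, tmp_path):
        with pytest.raises(BackendUnavailableError):
            DelimitedFileDatabase(tmp_path / "nope.csv")
        bad = tmp_path / "bad.csv"
        bad.write_text("id,comment\nx,\n")
        with pytest.raises(SchemaError):
            DelimitedFileDatabase(bad)

    def test_opening_does_not_modify_the_file(self, sample_csv):
        before = hashlib.sha256(sample_csv.read_bytes()).hexdigest()
        db = DelimitedFileDatabase(sample_csv)
        db.get_table()
        db.get_attributes()
        assert hashlib.sha256(sample_csv.read_bytes()).hexdigest() == before

    def test_open_database_dispatch(self, sample_csv):
        handle = open_database(sample_csv)
        assert len(handle.get_table().rows) == 3
        mem = open_database(make_table(2), backend="memory")
        assert len(mem.get_table().rows) == 2


class TestRead:
    def test_attributes_start_with_id_and_status(self, sample_database):
        attrs = sample_database.get_attributes()
        assert attrs[:2] == ["id", "status"]
        assert attrs == sample_database.get_table().header

    def test_snapshot_is_stable_without_writes(self, sample_database):
        first = sample_database.get_table()
        second = sample_database.get_table()
        assert [r.cells for r in first.rows] == [r.cells for r in second.rows]

    def test_external_append_is_visible_on_reread(self, sample_csv):
        db = DelimitedFileDatabase(sample_csv)
        assert len(db.get_table().rows) == 3
        with open(sample_csv, "a", newline="") as fh:
            csv.writer(fh).writerow(["extra", "", "", "", "", "0.7", "0.7"])
        # oracle: an independent raw parse of the same file
        assert len(raw_rows(sample_csv)) - 1 == 4
        assert db.get_table().job_ids()[-1] == "extra"


class TestWrite:
    def test_update_row_replaces_exactly_one_row(self, sample_database, sample_csv):
        before = raw_rows(sample_csv)
        completed = sample_database.get_row("default").replace(
            status="successful",
            **{"start-time": "2021-02-28 19:36:30", "end-time": "2021-02-28 19:38:20"},
        )
        assert sample_database.update_row("default", completed)
        after = raw_rows(sample_csv)
        assert after[1][:4] == ["default", "successful",
                               "2021-02-28 19:36:30", "2021-02-28 19:38:20"]
        assert after[0] == before[0] and after[2:] == before[2:]

    def test_identity_row_update_leaves_table_equal(self, sample_database, sample_csv):
        row = sample_database.get_row("attached")
        before = raw_rows(sample_csv)
        sample_database.update_row("attached", row)
        assert raw_rows(sample_csv) == before

    def test_update_row_unknown_id_leaves_file_untouched(self, sample_database,
                                                         sample_csv):
        before = sample_csv.read_bytes()
        row = sample_database.get_row("default")
        with pytest.raises(NotFoundError):
            sample_database.update_row("missing", row)
        assert sample_csv.read_bytes() == before

    def test_update_row_rejects_mismatched_attributes(self, sample_database):
        with pytest.raises(SchemaError):
            sample_database.update_row("default", JobRecord({"id": "default",
                                                             "status": ""}))

    def test_update_cell_changes_exactly_one_cell(self, sample_database, sample_csv):
        before = raw_rows(sample_csv)
        sample_database.update_cell("default", "status", "successful")
        after = raw_rows(sample_csv)
        diffs = [(i, j) for i in range(len(before))
                 for j in range(len(before[0])) if before[i][j] != after[i][j]]
        assert diffs == [(1, 1)]

    def test_update_cell_same_value_is_invisible(self, sample_database, sample_csv):
        sample_database.update_cell("default", "comment", "")
        assert raw_rows(sample_csv)[1][4] == ""
        assert len(raw_rows(sample_csv)) == 4

    def test_update_cell_unknown_targets(self, sample_database):
        with pytest.raises(NotFoundError):
            sample_database.update_cell("missing", "status", "x")
        with pytest.raises(NotFoundError):
            sample_database.update_cell("default", "no-such-column", "x")

    def test_round_trip_preserves_awkward_cell_strings(self, tmp_path):
        header = ["id", "status", "note"]
        values = ['a,b', 'quote "q"', 'new\nline', 'ünïcødé', ' spaced ']
        path = tmp_path / "tricky.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for i, v in enumerate(values):
                writer.writerow([f"j{i}", "", v])
        db = DelimitedFileDatabase(path)
        db.update_cell("j0", "status", "in progress")  # force a rewrite
        reread = DelimitedFileDatabase(path).get_table()
        assert [r.cells["note"] for r in reread.rows] == values

    def test_alternative_delimiter(self, tmp_path):
        path = tmp_path / "tabs.tsv"
        path.write_text("id\tstatus\tp\nj0\t\t0.5\n")
        db = DelimitedFileDatabase(path, delimiter="\t")
        db.update_cell("j0", "p", "0.25")
        assert DelimitedFileDatabase(path, delimiter="\t").get_row("j0").cells["p"] == "0.25"


class TestClaim:
    def test_claim_then_reclaim(self, sample_database):
        assert sample_database.claim_if_pending("default", "in progress")
        assert sample_database.get_row("default").status == "in progress"
        assert not sample_database.claim_if_pending("default", "in progress")
        assert sample_database.get_row("default").status == "in progress"

    def test_claim_unknown_id(self, sample_database):
        with pytest.raises(NotFoundError):
            sample_database.claim_if_pending("missing", "in progress")

    def test_cas_loses_to_interleaved_writer(self):
        db = InMemorySpreadsheet(make_table(1))

        def steal():
            db.interleave_hook = None  # only steal once
            db.update_cell("job000", "status", "in progress")

        db.interleave_hook = steal
        assert not db.claim_if_pending("job000", "mine")
        assert db.get_row("job000").status == "in progress"

    @pytest.mark.parametrize("backend", ["memory", "delimited"])
    def test_racing_workers_claim_each_row_once(self, backend, tmp_path):
        n_jobs, n_workers = 40, 8
        table = make_table(n_jobs)
        if backend == "memory":
            rng = random.Random(0)
            db = InMemorySpreadsheet(
                table, interleave_hook=lambda: rng.random() and None)
        else:
            path = tmp_path / "race.csv"
            with open(path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(table.header)
                for row in table.rows:
                    writer.writerow(list(row.cells.values()))
            db = DelimitedFileDatabase(path)
        claims: list[list[str]] = [[] for _ in range(n_workers)]

        def worker(k):
            for job_id in table.job_ids():
                if db.claim_if_pending(job_id, f"worker-{k}"):
                    claims[k].append(job_id)

        threads = [threading.Thread(target=worker, args=(k,))
                   for k in range(n_workers)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        won = [job for per_worker in claims for job in per_worker]
        assert sorted(won) == table.job_ids()
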