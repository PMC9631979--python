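"""Persistent run configuration stored as a JSON file.

Two keys are reserved for run state: ``last-test`` (the id of the job the
current worker most recently claimed, used to resume after a crash) and
``num-of-runs`` (how many jobs this session may start; -1 means all).
Every other key is user data — backend descriptors, credentials for
optional remote adapters, pipeline settings — and is preserved verbatim
across save cycles.  Saves are atomic (write to a temporary file, then
rename), so a crash never leaves a half-written config behind.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

LAST_TEST = "last-test"
NUM_OF_RUNS = "num-of-runs"

_DEFAULTS = {LAST_TEST: None, NUM_OF_RUNS: -1}


class NotFound:
    """Sentinel for a missing config key (distinct from a stored null)."""

    _instance: "NotFound | None" = None

    def __new__(cls) -> "NotFound":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "<not found>"


NOT_FOUND = NotFound()


class Config:
    """Key/value settings backed by a JSON file.

    Lookup is top-level only.  Reserved keys fall back to their defaults
    when absent from the file (``last-test`` -> None, ``num-of-runs`` ->
    -1, i.e. run every pending job).
    """

    def __init__(self, path: str | os.PathLike) -> None:
        self.path = Path(path)
        try:
            text = self.path.read_text(encoding="utf-8")
        except FileNotFoundError:
            raise FileNotFoundError(f"config file {self.path} does not exist") from None
        try:
            values = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(
                f"{self.path}: invalid JSON at line {exc.lineno}, "
                f"column {exc.colno}: {exc.msg}"
            ) from None
        if not isinstance(values, dict):
            raise ValueError(f"{self.path}: top-level JSON value must be an object")
        self.values: dict = values

    def get_value(self, key: str):
        """Return the stored value, a reserved default, or NOT_FOUND."""
        if key in self.values:
            return self.values[key]
        if key in _DEFAULTS:
            return _DEFAULTS[key]
        return NOT_FOUND

    def set_value(self, key: str, value) -> None:
        """Set a key and persist the whole store to disk immediately."""
        self.values[key] = value
        self.save()

    def save(self) -> None:
        tmp = self.path.with_name(self.path.name + ".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(self.values, fh, indent=2)
            fh.write("\n")
            fh.flush()
            os.fsync(fh.fileno())
        os.replace(tmp, self.path)

    # run-state conveniences -------------------------------------------------

    @property
    def last_test(self) -> str | None:
        return self.get_value(LAST_TEST)

    @property
    def num_of_runs(self) -> int:
        value = self.get_value(NUM_OF_RUNS)
        if not isinstance(value, int) or isinstance(value, bool):
            raise ValueError(f"{NUM_OF_RUNS} must be an integer, got {value!r}")
        return value


def default_config(path: str | os.PathLike) -> Config:
    """Write a fresh config file with the default run state and load it."""
    path = Path(path)
    path.write_text(json.dumps(dict(_DEFAULTS)) + "\n", encoding="utf-8")
    return Config(path)
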