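"""XML settings injection and fixture generation.

Agent-based simulators commonly read their run settings from an XML file.
To sweep a parameter, a job names it by its element path from the
document root — e.g. ``/user_parameters/attached_worker_migration_bias``
for the ``<attached_worker_migration_bias>`` tag nested inside
``<user_parameters>`` — and :func:`apply_parameters` writes the job's
value into that element's text.  The testing script never hard-codes
which settings it edits: adding a column to the database is enough to
sweep a new parameter.

A leading ``/`` distinguishes injectable element paths from metadata
attributes (``id``, ``status``, timestamps, ...), which are skipped and
reported rather than written.
"""

from __future__ import annotations

import csv
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UnresolvedPathError


@dataclass
class InjectionReport:
    """Which mapping keys were written into the document and which skipped."""

    written: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def apply_parameters(params: dict[str, str],
                     settings_in: str | os.PathLike,
                     settings_out: str | os.PathLike | None = None
                     ) -> InjectionReport:
    """Write parameter values into an XML settings file by element path.

    For every key starting with ``/``, the first element (in document
    order) matching the path's segments in sequence gets its text replaced
    by the value, verbatim.  Keys without a leading ``/`` are skipped and
    listed in the report.  Everything else in the document — untargeted
    elements, attributes, structure — is preserved.  ``settings_out``
    defaults to ``settings_in`` (in-place update).

    Raises :class:`UnresolvedPathError` for a path matching no element;
    missing elements are never created silently.
    """
    settings_in = Path(settings_in)
    settings_out = Path(settings_out) if settings_out is not None else settings_in
    tree = ET.parse(settings_in)
    root = tree.getroot()
    report = InjectionReport()
    for key, value in params.items():
        if not key.startswith("/"):
            report.skipped.append(key)
            continue
        relative = key.lstrip("/")
        element = root.find(relative)
        if element is None:
            raise UnresolvedPathError(
                f"path {key!r} does not resolve to any element in {settings_in}"
            )
        element.text = str(value)
        report.written.append(key)
    tree.write(settings_out, encoding="utf-8", xml_declaration=True)
    return report


# column names used by the bundled example database: the two migration
# biases of the cargo-delivery ("biorobots") model, as element paths
ATTACHED_BIAS_PATH = "/user_parameters/attached_worker_migration_bias"
UNATTACHED_BIAS_PATH = "/user_parameters/unattached_worker_migration_bias"

_SAMPLE_HEADER = ["id", "status", "start-time", "end-time", "comment",
                  ATTACHED_BIAS_PATH, UNATTACHED_BIAS_PATH]

# three jobs: the model's defaults, a weakly-biased attached phase, and a
# weakly-biased unattached phase
_SAMPLE_ROWS = [
    ["default", "", "", "", "", "1.0", "0.5"],
    ["attached", "", "", "", "", "0.1", "1.0"],
    ["unattached", "", "", "", "", "1.0", "0.1"],
]


def sample_db(path: str | os.PathLike, delimiter: str = ",") -> Path:
    """Write the three-job example parameter database and return its path."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_SAMPLE_HEADER)
        writer.writerows(_SAMPLE_ROWS)
    return path


_SETTINGS_SKELETON = """\
<?xml version="1.0" encoding="UTF-8"?>
<settings>
    <domain>
        <x_min>-400</x_min>
        <x_max>400</x_max>
        <y_min>-400</y_min>
        <y_max>400</y_max>
    </domain>
    <overall>
        <max_time units="min">2880</max_time>
    </overall>
    <save>
        <folder>output</folder>
    </save>
    <user_parameters>
        <random_seed type="int" units="dimensionless">0</random_seed>
        <attached_worker_migration_bias type="double" units="dimensionless">1.0</attached_worker_migration_bias>
        <unattached_worker_migration_bias type="double" units="dimensionless">0.5</unattached_worker_migration_bias>
        <number_of_workers type="int" units="dimensionless">5</number_of_workers>
        <number_of_cargo type="int" units="dimensionless">10</number_of_cargo>
    </user_parameters>
</settings>
"""


def sample_settings(path: str | os.PathLike) -> Path:
    """Write a minimal simulation-settings XML skeleton and return its path.

    The layout mirrors the settings files of grid-based agent simulators:
    a spatial domain, an overall clock, and a ``<user_parameters>`` block
    holding the model-specific knobs, including the two migration biases
    the example database sweeps.
    """
    path = Path(path)
    path.write_text(_SETTINGS_SKELETON, encoding="utf-8")
    return path
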