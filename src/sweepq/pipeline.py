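"""The end-to-end model-exploration loop.

A pipeline run repeatedly claims the next pending job, injects its
parameters into the XML settings file, labels the job with the task being
performed, executes the simulator (the bundled toy model or an external
command), and marks the job successful or failed — then claims the next
one.  The database is mutated in place throughout, so anyone watching the
shared table sees live progress.
"""

from __future__ import annotations

import logging
import os
import platform
import shlex
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

from .biorobots import load_parameters_from_settings, run_toy_simulation
from .config import Config
from .db import Database
from .inject import apply_parameters
from .manager import ParameterManager
from .records import JobRecord

log = logging.getLogger(__name__)

TASK_LABEL = "running simulation"


@dataclass
class JobTiming:
    job_id: str
    status: str
    seconds: float


@dataclass
class PipelineReport:
    jobs_attempted: int = 0
    jobs_successful: int = 0
    jobs_failed: int = 0
    timings: list[JobTiming] = field(default_factory=list)


def toy_simulator_executor(job: JobRecord, settings_path: Path,
                           output_dir: Path) -> None:
    """Built-in executor: run the toy cargo-delivery model.

    Reads the (already injected) settings file and writes snapshots and a
    summary under ``output_dir/<job id>/``.
    """
    params = load_parameters_from_settings(settings_path)
    run_toy_simulation(params, output_dir / job.id)


def command_executor(template: str):
    """Executor dispatching an external command per job.

    ``template`` may contain ``{settings}``, ``{output_dir}`` and ``{id}``
    placeholders.  The command is run through the platform shell (shell
    conventions for launching executables differ between Windows and
    Unix-like systems); a nonzero exit status raises and the job is
    marked failed.
    """

    def run(job: JobRecord, settings_path: Path, output_dir: Path) -> None:
        command = template.format(settings=settings_path,
                                  output_dir=output_dir / job.id, id=job.id)
        if platform.system() == "Windows":  # pragma: no cover
            argv: list[str] | str = command
            shell = True
        else:
            argv = shlex.split(command)
            shell = False
        result = subprocess.run(argv, shell=shell, capture_output=True, text=True)
        if result.returncode != 0:
            tail = (result.stderr or result.stdout or "").strip().splitlines()[-1:]
            raise RuntimeError(
                f"command exited with status {result.returncode}"
                + (f": {tail[0]}" if tail else "")
            )

    return run


def run_pipeline(db: Database, settings_path: str | os.PathLike,
                 config: Config | None = None,
                 executor=toy_simulator_executor,
                 output_dir: str | os.PathLike = "output") -> PipelineReport:
    """Run jobs until the database has no more work for this session.

    Per job: claim -> inject parameters into the settings file -> set the
    status to a task label -> execute -> mark successful, or failed (with
    the reason in the comment) if the executor raises.  Honors the
    config's ``num-of-runs`` limit and resumes an interrupted job first.
    """
    settings_path = Path(settings_path)
    output_dir = Path(output_dir)
    manager = ParameterManager(db, config)
    report = PipelineReport()

    job = manager.next_parameters()
    while job is not None:
        report.jobs_attempted += 1
        started = time.monotonic()
        try:
            injection = apply_parameters(job.params, settings_path)
            log.info("job %s: injected %d parameter(s)", job.id,
                     len(injection.written))
            manager.update_status(job.id, TASK_LABEL)
            executor(job, settings_path, output_dir)
        except Exception as exc:
            manager.failed(job.id, str(exc))
            report.jobs_failed += 1
            report.timings.append(
                JobTiming(job.id, "failed", time.monotonic() - started))
        else:
            manager.successful(job.id)
            report.jobs_successful += 1
            report.timings.append(
                JobTiming(job.id, "successful", time.monotonic() - started))
        job = manager.next_parameters()
    log.info("pipeline done: %d attempted, %d successful, %d failed",
             report.jobs_attempted, report.jobs_successful, report.jobs_failed)
    return report
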