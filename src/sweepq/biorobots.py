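"""A deterministic toy cargo-delivery ("biorobots") agent simulation.

Worker agents drag cargo agents toward a director.  Each worker takes
steps of fixed length; its step direction blends a unit vector toward its
current target with a uniformly random unit vector:

    direction = normalize(b * t_hat + (1 - b) * u)

where ``t_hat`` points at the target and ``u`` is random.  The migration
bias ``b`` lies in [0, 1]: at 0 the path is a pure random walk, at 1 it
is a deterministic straight line.  An unattached worker heads for the
nearest free cargo with bias ``unattached_bias``; on contact (within
``delivery_radius``) it picks the cargo up and heads for the director
with bias ``attached_bias``; within ``delivery_radius`` of the director
the cargo is delivered and the worker is free again.

The model exists so a full parameter-sweep pipeline — database, claim,
settings injection, execution, storage — can run end to end in seconds
with analytically checkable dynamics.  It makes no attempt to reproduce
the mechanics or diffusion of a full multicellular simulator.
"""

from __future__ import annotations

import json
import math
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SimulationParameters:
    """Inputs of one simulation run.  All randomness is fixed by ``seed``."""

    attached_bias: float = 1.0      # b_a, dimensionless in [0, 1]
    unattached_bias: float = 0.5    # b_u, dimensionless in [0, 1]
    n_workers: int = 5
    n_cargo: int = 10
    n_steps: int = 200
    step_length: float = 1.0        # arena units per step
    delivery_radius: float = 0.5    # contact distance, arena units
    arena_size: float = 100.0       # side of the square placement region
    seed: int = 0
    # explicit placements override random placement (for reproducible
    # geometric scenarios); director defaults to the arena center
    worker_positions: list[tuple[float, float]] | None = None
    cargo_positions: list[tuple[float, float]] | None = None
    director_position: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        for name, b in (("attached_bias", self.attached_bias),
                        ("unattached_bias", self.unattached_bias)):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {b}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be positive")
        if self.n_cargo < 0:
            raise ValueError("n_cargo must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if self.step_length <= 0 or self.delivery_radius <= 0:
            raise ValueError("step_length and delivery_radius must be positive")


@dataclass
class SimulationSummary:
    """Outputs of one run."""

    delivered_count: int
    delivered_fraction: float
    mean_final_distance: float | None   # mean cargo→director distance; None if no cargo
    mean_squared_displacement: float    # of workers, final vs initial
    delivery_steps: list[int]           # step index at which each delivery happened
    snapshot_paths: list[str] = field(default_factory=list)


def run_toy_simulation(params: SimulationParameters,
                       output_dir: str | os.PathLike | None = None
                       ) -> SimulationSummary:
    """Run the cargo-delivery model; deterministic for fixed params + seed.

    When ``output_dir`` is given, three agent-position snapshots (initial,
    middle, final — delimited text) and a ``summary.json`` are written
    there.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    half = params.arena_size / 2.0

    if params.worker_positions is not None:
        workers = np.array(params.worker_positions, dtype=float).reshape(-1, 2)
        if len(workers) != params.n_workers:
            raise ValueError("worker_positions length must equal n_workers")
    else:
        workers = rng.uniform(-half, half, size=(params.n_workers, 2))
    if params.cargo_positions is not None:
        cargo = np.array(params.cargo_positions, dtype=float).reshape(-1, 2)
        if len(cargo) != params.n_cargo:
            raise ValueError("cargo_positions length must equal n_cargo")
    else:
        cargo = rng.uniform(-half, half, size=(params.n_cargo, 2))
    director = np.asarray(params.director_position, dtype=float)

    initial_workers = workers.copy()
    # cargo state: 0 free, 1 carried, 2 delivered
    cargo_state = np.zeros(params.n_cargo, dtype=int)
    carrying = np.full(params.n_workers, -1, dtype=int)  # cargo index or -1
    delivery_steps: list[int] = []

    snapshots: list[str] = []
    snapshot_steps = {0, params.n_steps // 2, params.n_steps}
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        snapshots.append(_write_snapshot(out, 0, workers, cargo, cargo_state,
                                         director))

    for step in range(1, params.n_steps + 1):
        # one random unit vector per worker per step, drawn in worker order
        theta = rng.uniform(0.0, 2.0 * math.pi, size=params.n_workers)
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        for i in range(params.n_workers):
            if carrying[i] >= 0:
                target, bias = director, params.attached_bias
            else:
                free = np.flatnonzero(cargo_state == 0)
                if free.size:
                    d = np.linalg.norm(cargo[free] - workers[i], axis=1)
                    target, bias = cargo[free[np.argmin(d)]], params.unattached_bias
                else:
                    target, bias = None, 0.0
            if target is None:
                direction = u[i]
            else:
                to_target = target - workers[i]
                dist = np.linalg.norm(to_target)
                t_hat = to_target / dist if dist > 0 else np.zeros(2)
                blended = bias * t_hat + (1.0 - bias) * u[i]
                norm = np.linalg.norm(blended)
                direction = blended / norm if norm > 1e-12 else u[i]
            workers[i] = workers[i] + params.step_length * direction

            if carrying[i] >= 0:
                cargo[carrying[i]] = workers[i]
                if np.linalg.norm(workers[i] - director) <= params.delivery_radius:
                    cargo_state[carrying[i]] = 2
                    delivery_steps.append(step)
                    carrying[i] = -1
            else:
                free = np.flatnonzero(cargo_state == 0)
                if free.size:
                    d = np.linalg.norm(cargo[free] - workers[i], axis=1)
                    j = int(np.argmin(d))
                    if d[j] <= params.delivery_radius:
                        cargo_state[free[j]] = 1
                        carrying[i] = int(free[j])
        if out is not None and step in snapshot_steps:
            snapshots.append(_write_snapshot(out, step, workers, cargo,
                                             cargo_state, director))

    delivered = int(np.count_nonzero(cargo_state == 2))
    if params.n_cargo:
        mean_dist = float(np.mean(np.linalg.norm(cargo - director, axis=1)))
        fraction = delivered / params.n_cargo
    else:
        mean_dist = None
        fraction = 0.0
    msd = float(np.mean(np.sum((workers - initial_workers) ** 2, axis=1)))
    summary = SimulationSummary(
        delivered_count=delivered,
        delivered_fraction=fraction,
        mean_final_distance=mean_dist,
        mean_squared_displacement=msd,
        delivery_steps=delivery_steps,
        snapshot_paths=snapshots,
    )
    if out is not None:
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump({
                "delivered_count": summary.delivered_count,
                "delivered_fraction": summary.delivered_fraction,
                "mean_final_distance": summary.mean_final_distance,
                "mean_squared_displacement": summary.mean_squared_displacement,
                "delivery_steps": summary.delivery_steps,
                "snapshot_paths": summary.snapshot_paths,
            }, fh, indent=2)
            fh.write("\n")
    return summary


def _write_snapshot(out: Path, step: int, workers, cargo, cargo_state,
                    director) -> str:
    """Agent positions at one step, as delimited text."""
    path = out / f"snapshot_step{step:06d}.csv"
    states = {0: "free", 1: "carried", 2: "delivered"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("agent_type,agent_id,x,y,state\n")
        fh.write(f"director,0,{director[0]:.6f},{director[1]:.6f},fixed\n")
        for i, (x, y) in enumerate(workers):
            fh.write(f"worker,{i},{x:.6f},{y:.6f},active\n")
        for i, (x, y) in enumerate(cargo):
            fh.write(f"cargo,{i},{x:.6f},{y:.6f},{states[int(cargo_state[i])]}\n")
    return str(path)


# element names recognized inside <user_parameters>, mapped to fields
_XML_FIELDS = {
    "attached_worker_migration_bias": ("attached_bias", float),
    "unattached_worker_migration_bias": ("unattached_bias", float),
    "random_seed": ("seed", int),
    "number_of_workers": ("n_workers", int),
    "number_of_cargo": ("n_cargo", int),
    "number_of_steps": ("n_steps", int),
    "step_length": ("step_length", float),
    "delivery_radius": ("delivery_radius", float),
    "arena_size": ("arena_size", float),
}


def load_parameters_from_settings(settings_file: str | os.PathLike
                                  ) -> SimulationParameters:
    """Build :class:`SimulationParameters` from an XML settings file.

    The two migration-bias elements must be present under
    ``<user_parameters>``; any other recognized element overrides its
    default.  Raises ``ValueError`` on missing biases, non-numeric text,
    or out-of-range values.
    """
    root = ET.parse(settings_file).getroot()
    block = root.find("user_parameters")
    if block is None:
        raise ValueError(f"{settings_file}: no <user_parameters> element")
    kwargs: dict = {}
    for tag, (attr, cast) in _XML_FIELDS.items():
        element = block.find(tag)
        if element is None:
            continue
        text = (element.text or "").strip()
        try:
            kwargs[attr] = cast(text)
        except ValueError:
            raise ValueError(
                f"{settings_file}: <{tag}> text {text!r} is not a valid {cast.__name__}"
            ) from None
    for required in ("attached_bias", "unattached_bias"):
        if required not in kwargs:
            raise ValueError(
                f"{settings_file}: missing migration-bias element for {required}"
            )
    params = SimulationParameters(**kwargs)
    params.validate()
    return params
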