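# sweepq

A serverless, table-backed job queue for distributed simulation parameter
sweeps.

## The problem

Evaluating a simulation model — an agent-based multicellular model, say —
means running it over many parameter sets (model exploration / grid
search). Small teams rarely have a scheduler for this: one person ends up
babysitting every run on their own machine. sweepq removes the server
from the picture entirely. The parameter sets live as rows of a shared
**table** (a CSV file, or an online spreadsheet behind the same adapter
interface); each worker process claims the next pending row atomically,
runs the simulation it describes, and writes the outcome back into the
row. Anyone who can see the table can add a worker, so a team can pool
idle desktops into an ad hoc compute pool with nothing to deploy.

## How it works

Each **job** is one row: a unique `id`, a `status`, optional
`start-time` / `end-time` / `comment` metadata, and the parameter values.
The status lifecycle is

```
""  (pending)  →  "in progress"  →  free-form task labels  →  "successful" | "failed"
```

The claim primitive is compare-and-swap on the status cell: a claim
succeeds iff the status is still empty at write time (the file backend
serializes claims under an exclusive advisory lock; the in-memory
spreadsheet mock uses a mutex-guarded CAS). This guarantees each job runs
exactly once even with many concurrent workers. A JSON run config
persists `last-test` (the current job id, so a crashed worker resumes the
same job on restart) and `num-of-runs` (how many jobs a session may
start; -1 means all).

Parameter columns whose names begin with `/` are XML element paths —
`/user_parameters/attached_worker_migration_bias` names the
`<attached_worker_migration_bias>` element inside `<user_parameters>` —
and are injected verbatim into the simulator's settings file before each
run, so sweeping a new parameter means adding a column, not editing code.

The bundled toy simulator is a cargo-delivery ("biorobots") model: worker
agents drag cargo toward a director, stepping along
`normalize(b·t̂ + (1−b)·u)` with `t̂` the unit vector to the target, `u` a
random unit vector, and migration bias `b ∈ [0,1]` interpolating between
a pure random walk (b = 0) and deterministic straight-line motion
(b = 1). It exists so the whole pipeline runs end to end in seconds with
analytically checkable behavior; see `docs/methods.md`.

## Worked example

```
$ sweepq init --dir demo
wrote parameters.csv, config.json and settings.xml in demo
$ sweepq status --db demo/parameters.csv
pending: 3
in progress: 0
successful: 0
failed: 0
$ sweepq run --config demo/config.json --db demo/parameters.csv \
             --settings demo/settings.xml --output-dir demo/output
attempted 3, successful 3, failed 0
$ sweepq status --db demo/parameters.csv
pending: 0
in progress: 0
successful: 3
failed: 0
```

`init` writes a three-job example database (`default`, `attached`,
`unattached` — each a different pair of migration biases), a default
config `{"last-test": null, "num-of-runs": -1}`, and a settings skeleton.
`run` claims each job in turn, injects its biases into the settings file,
runs the toy simulator, and stamps the row: afterwards `parameters.csv`
shows every status `successful` with `start-time`/`end-time` filled in
(`YYYY-MM-DD HH:MM:SS`), and `demo/output/<job id>/` holds three
agent-position snapshots (initial / middle / final) plus a
`summary.json` with the delivered-cargo count and fraction. The same
loop is available in Python via `sweepq.run_pipeline(...)`, and
`--command "TEMPLATE"` swaps the toy simulator for any external
executable.

Crash behavior: kill a worker mid-job and rerun — the interrupted job is
re-yielded first (via `last-test`), and no job is ever executed twice to
success.

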