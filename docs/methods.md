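# Methods

## Coordination model

sweepq is a database-centric (serverless) work queue. The only shared
state is the parameter table; there is no job-distribution server and no
message passing between workers. Correctness therefore rests on one
primitive, `claim_if_pending(job_id, label)`: atomically set the status
cell to `label` if and only if it is still the empty string. Everything
else — progress labels, completion marks, cross-job edits — is plain
last-writer-wins cell writing, which is intentional: coordination on a
shared spreadsheet is trust-based, and the package does not try to add
ownership enforcement the medium cannot provide.

Rows are addressed by their mandatory, unique `id`, never by position,
so concurrent appends or reordering by other users cannot retarget a
write. Duplicate ids are rejected at open time as a hard schema error;
tolerating them would make "claimed exactly once" meaningless. All cell
values are strings and round-trip verbatim; the empty string in `status`
is the pending marker, `successful` and `failed` are the two terminal
values, and any other non-empty value is a free-form label for the task
currently executing.

### File backend

The delimited backend (CSV by default, configurable delimiter, UTF-8,
mandatory header) rewrites the whole file to a temporary path and
renames it into place, with every read-modify-write cycle — including
the claim — executed under an exclusive advisory lock on a sidecar
`<name>.lock` file (`flock`, with an `O_EXCL` lock-file fallback on
platforms without it). Rename gives readers atomic visibility (they see
the old file or the new one, never a torn write); the lock serializes
writers, which makes claims safe for multiple processes on one
filesystem. Lock acquisition has a timeout (default 10 s) and raises a
retryable contention error rather than blocking forever.

### In-memory spreadsheet mock

Remote spreadsheet services are represented in the test suite by an
in-memory backend implementing the same adapter contract. Its claim
follows the pattern a remote client must use: an optimistic read, then a
check-and-set that re-validates the status immediately before writing
(here under a mutex). A deliberate hook between the read and the CAS
lets tests inject adversarial schedules — sleeps, thread yields,
competing writes — so claim exclusivity is exercised under contention
rather than assumed. A live spreadsheet adapter would implement the same
contract and must document its own consistency guarantees; it is an
optional extra and deliberately not part of the offline test surface.

## Job lifecycle

`next_parameters()` resolves in this order:

1. **Resume.** If the config's `last-test` names a job whose status is
   neither `successful` nor `failed`, that job is returned again. This
   is what makes a kill-and-restart complete the sweep without either
   abandoning or double-running the interrupted job. A resumed job does
   not count against `num-of-runs`: it was started by the crashed
   session, and the limit caps session *starts*.
2. **Run limit.** With `num-of-runs = n ≥ 0, a session starts at most n
   jobs; the counter lives in memory and is checked before scanning.
   The limit is read once at manager construction and never decremented
   in the config file — it describes session behavior, not persistent
   state.
3. **Scan and claim.** The first row in table order with an empty status
   (and accepted by the optional claim predicate, e.g. "skip jobs that
   need more compute than this machine has") is claimed via the CAS. If
   another worker steals it between read and claim, the next candidate
   is tried; after exhausting a snapshot's candidates the table is
   re-read, up to a bounded number of rescans, then the no-more-work
   sentinel (`None`) is returned.

On a successful claim the status becomes `in progress`, `start-time` is
stamped (local time, `YYYY-MM-DD HH:MM:SS`) if that column exists, and
`last-test` is persisted before the job is handed to the caller, so a
crash at any later point is recoverable. `successful()` and `failed()`
stamp `end-time` and clear `last-test`; `failed()` appends its reason to
the `comment` cell. Re-running a parameter set is done by adding a new
row with a fresh id; there is deliberately no in-place reset, which
would reintroduce double-execution races.

## Settings injection

Parameter columns are either plain names (metadata) or, with a leading
`/`, element paths into the simulator's XML settings file. A path
resolves to the first element in document order matching its segments
from the root; indexed access to repeated siblings is not supported (a
documented limitation — the first match wins). Injection replaces only
the targeted elements' text, verbatim (no numeric reformatting);
unresolved paths raise rather than silently creating elements, because a
typo that silently no-ops would corrupt a sweep. The serializer may
normalize cosmetic whitespace/quoting, so fidelity is defined — and
tested — on canonicalized trees, not raw bytes.

## Run configuration

A flat JSON object; lookup is top-level only. Absent reserved keys
default to `last-test = null`, `num-of-runs = -1` (run everything).
Unknown keys — user values, adapter credentials under namespaced keys —
are preserved verbatim across save cycles. Saves are
write-temp-then-rename, so no partial write is ever visible.

## Storage

A minimal transfer contract (connect / upload / download / delete /
rename, plus recursive folder forms) behind which cloud services plug
in. The reference backend is a sandboxed local folder: transfers are
byte-faithful copies, remote paths are confined to the root
(parent-directory escapes are rejected), rename refuses to clobber an
existing target, and overwriting uploads are allowed but logged. This
keeps the entire suite offline while exercising the exact surface a
cloud adapter must satisfy.

## The toy cargo-delivery simulator

The bundled model exists so the full pipeline — claim, injection,
execution, bookkeeping, storage — runs at desk scale with analytically
checkable dynamics. It is this package's own minimal construction and
claims no quantitative agreement with any full multicellular simulator:
no diffusion, no mechanics, no cell cycle.

**Dynamics.** Workers, cargo, and a director live in a 2-D arena. Each
step a worker moves a fixed `step_length` along
`normalize(b·t̂ + (1−b)·u)`, where `t̂` points at its target (nearest
free cargo when unattached, using `unattached_bias`; the director when
carrying, using `attached_bias`) and `u` is a fresh uniform random unit
vector. Contact within `delivery_radius` picks a cargo up or, at the
director, delivers it. With no remaining target the step is `u` — a pure
random walk. Agents update in fixed order with one random draw per
worker per step, so a fixed `(parameters, seed)` pair reproduces
bit-identical outputs.

**Parameters** (defaults): `attached_bias` = 1.0 and `unattached_bias` =
0.5 (dimensionless, in [0, 1] — the pair swept by the example database),
5 workers, 10 cargo, 200 steps, `step_length` = 1.0 and
`delivery_radius` = 0.5 arena units, placement region 100×100 centered
on the director. Explicit agent positions can be supplied for geometric
test scenarios.

**Analytic anchors.** At `b = 1` motion is exactly collinear, so a
worker 10 units from a cargo that is 20 units from the director delivers
at precisely step 30 (exact integer assertion). At `b = 0` the walk is a
sum of i.i.d. unit steps, so E[|x_T|²] = T·step²; with
Var(|x_T|²) = T(T−1) the mean over N independent seeds has standard
error ≈ T/√N, and the suite asserts agreement within 4σ (T = 100,
N = 1000 in the acceptance script — about a 13% band, met with ~1–3%
error in practice). Mean final cargo-to-director distance decreases
monotonically in `attached_bias` (checked over 200 seeds at three bias
levels). Outputs are three agent-position snapshots (delimited text, at
steps 0, T/2, T) and a JSON summary; plotting is intentionally omitted.

**What passing these tests shows — and not.** They validate the
*pipeline*: exclusivity, resume, injection, bookkeeping, and that the
executor seam behaves. They say nothing about any real simulator's
science; with an external command template the executor's correctness is
the user's.

## Numerical and design choices

- Timestamps are local time without timezone, matching the table format
  users see in a spreadsheet; ordering assertions only ever compare
  timestamps written by the same host.
- The in-loop task label is `running simulation`; user pipelines may
  overwrite it with finer-grained labels at will.
- An external command exiting nonzero marks the job `failed` (reason in
  `comment`) and the loop continues; there are no retries, priorities,
  or job dependencies — a transient failure is re-run by adding a new
  row.
- Blend-vector degeneracy: if `b·t̂ + (1−b)·u` is numerically zero
  (opposed vectors at b = 0.5), the random direction is used.
- Problem sizes in the test suite and acceptance script (100-job races,
  100 randomized oracle tables, 1000 random-walk seeds, ≤200-step
  simulations) were chosen so the whole suite completes in seconds while
  keeping Monte-Carlo standard errors a few percent — small enough to
  iterate on, large enough that the statistical assertions have teeth.

## Known limitations

- The file backend's advisory lock protects cooperating sweepq processes
  on one filesystem; it cannot stop a non-cooperating editor from
  corrupting the table mid-sweep.
- Claim fairness is not guaranteed — a fast worker may claim most jobs;
  only exclusivity is.
- XML injection targets element text only (no attributes) and cannot
  address the n-th of repeated sibling tags.
- The spreadsheet mock models consistency, not latency or API quota
  behavior of a real service.
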