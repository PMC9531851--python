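# Methods

This note records how the pieces work, the parameters that matter, and the
design choices made where more than one reasonable convention existed.

## The channel protocol

A channel is one shared directory holding one text file per payload. A
message is `[simtime,v1,...,vn]`: a real simulation timestamp followed by a
flat real vector (matrices must be flattened by the caller; the payload is
deliberately one-dimensional). Values are formatted with Python's
shortest-round-trip `repr`, so `parse(serialize(m)) == m` holds exactly at
full double precision. That matters twice over: change detection compares
file text byte-for-byte, and the equality guarantees below are *exact*, not
approximate.

A reader polls: it re-reads its inputs, sleeping `delay` seconds between
rounds, until some input's text differs from the last accepted text. Three
file states are legal — identical (keep polling), changed (proceed), and
zero-length (a writer reopened the file but has not yet written; keep
polling and count it in `retrycount`). A missing file at start-up is
replaced by a caller-supplied *initial string*, which breaks the
chicken-and-egg dependency between the two halves of a loop. Anything else
is malformed; transient malformed reads (a partially flushed write) are
retried up to `malformed_limit` (200) before the channel is declared
corrupt.

Writes advance the node's simulation time by `delta ≥ 0` **before**
serializing, so the written stamp is the advanced one and a loop guarded by
`simtime < maxtime` terminates right after writing the horizon value. Reads
take `simtime := max(simtime, stamp)` across all inputs; time is therefore
non-decreasing everywhere. The default write mode truncates in place,
preserving the three-state contract above; an `atomic` mode (write-temp,
rename) is available and removes the zero-byte state entirely.

**Parameters.** `delay` defaults to 0.01 s — within the 0.005–0.02 s range
that keeps `retrycount` around 10 % of simulation cycles on commodity
hardware; it is the per-edge latency floor. `maxtime` defaults to 300 and is
normally broadcast into every edge directory as a `concore.maxtime` file
(the study `maxtime` verb); a node takes the maximum over the files it can
see.

**Start-up determinism.** If every node "fires" once from its initial string
(the laissez-faire convention), the first few exchanges depend on process
scheduling: a fast plant can overwrite the initial before a slow controller
reads it. We make initiation explicit instead: `read_port` registers the
initial string as the change-detection baseline by default (strictly
reactive), and the single loop-initiating node passes `fire_on_initial=True`
so its first read counts as new. With exactly one initiator per loop, every
node consumes each peer message exactly once in order, and the trajectory is
independent of scheduling — which is what lets the tests demand *element-wise
identical* trajectories across execution modes. In the cardiac demo the
plant initiates (it also paces time with `delta = 1` per beat); the
controller answers with `delta = 0`, its stamps advancing through the reads.
The power meter initiates on its controller-facing port for the same reason.

Reads with `register=False` never participate in change detection: they are
for optional, non-pacing inputs (the testbench knob), read fresh each beat
with a default fallback.

**Fault injection.** `RuntimeState.fault_rate`/`fault_seed` drive a seeded
injector that makes a poll observe the zero-byte state regardless of actual
file content — exactly what a reader sees when it catches the writer
mid-truncate, but reproducible. The physical race itself is exercised
separately by an adversarial-writer thread test.

## Workflow graphs and studies

Workflows are directed graphs with cycles; GraphML is accepted with labels
either as plain `label` attributes or nested inside `<data>` elements (the
style of graphical editors). Node labels classify nodes: a recognized source
extension (`.py .sh .m .cpp .v`) after the colon means a launchable program;
no extension means a prebuilt container image; a bare name or trailing colon
means a null node (no program — it exists to expose a persistent channel).
An unrecognized extension is an error rather than a guess. Edge labels must
be globally unique because they name the shared directories.

Port numbers are assigned in document order, 1..k per node per direction.
The original tooling never states its rule; any deterministic order works,
and document order is the one a user can see. Liveness warnings (open-loop
graph, null node inside a cycle, nodes disconnected from every cycle) are
advisory, not fatal: an open-loop graph is a legitimate pipeline.

A *study* realizes the graph: node directories with a copy of their source,
edge directories, and symbolic links binding `NODE/out<i>` and `NODE/in<j>`
to the edge directory — the contract is "two paths, one directory", and the
tests assert the contract rather than the mechanism. A
`concore_ports.json` registry in each node directory records the
label→index maps so node programs can address ports symbolically. `clear`
deletes channel payloads but keeps `concore.maxtime` (clearing data should
not forget the configured horizon); a re-run without `clear` warm-starts
from the surviving channel files. Container plans mirror the linked layout
with named volumes (volume name = edge label), out-ports mounted read-write
at `/out<k>` and in-ports read-only at `/in<k>`; prebuilt images skip the
build step, and a per-node `<stem>.Dockerfile` overrides the default build
spec. Plan generation is always available; executing containers requires a
runtime and is refused cleanly without one.

## The mediator

The mediator is a store-and-forward HTTP service for loops that span sites.
Sessions are directories named `sanitize(dirname)_apikey`; the sanitizer
replaces path separators, `..` sequences and control characters with `_`,
and the same rule is applied to payload names, so no request can read or
write outside its own session. Authentication is a static API-key registry
checked on every request (provisioning keys is a deployment concern, not a
protocol one). `/init` stores initial payload values (re-init replaces
them), `/cleanup` removes the session idempotently, and `/ctl` and `/pm` are
symmetric exchange endpoints distinguished only by convention — each stores
the caller's uploads and returns the requested payload, every file access
under a per-file lock so a fetched payload is always a complete previously
stored message.

A *wrapper* stands in for the missing peer: it watches its local node's
output file, posts new text verbatim to the mediator while fetching the peer
payload, and delivers the fetched text verbatim (timestamp included) once
the peer's simulation time changes — text in, text out, so the mediated loop
is byte-identical to the local one. Peer-change detection is by timestamp,
which is why the pacing node's `delta = 1` matters end-to-end. Transient
HTTP failures are simply retried; the wrapper aborts only after a
configurable period with no progress (default deadline 60 s, re-post
interval 0.5 s; the localhost tests shorten both). Wrappers do not call
`/init` themselves — the orchestrator initializes the session once, which
avoids a late wrapper's re-init clobbering a live exchange.

## The cardiac demonstration

The plant is `x(t+1) = A x(t) + B u(t)`, `ym(t+1) = C x(t) + D u(t)`, one
step per heartbeat. `u ∈ R⁶` packs three stimulation sites as (frequency,
pulse width) pairs, box-limited to 0–50 Hz and 0–1 ms; `ym = (MAP, HR)` in
mmHg and bpm. The HR-at-index-1 ordering is forced by the power meter's
`period = 60/ym[1]`, which is only dimensionally sensible if index 1 is a
rate; the ordering is a named convention throughout.

No canonical plant matrices are published, so `generate_stable_system` draws
them: Gaussian entries, `A` rescaled to spectral radius 0.9, candidates
rejected until the DC gain `C(I−A)⁻¹B + D` has rank 2 so that two-output
setpoints are reachable. `make_demo_system` further rescales the output rows
so the demo setpoint — 110.4 mmHg and 374.5 bpm, a rat's operating point —
is exactly the steady-state image of the middle of the stimulation box.
Everything is deterministic per seed.

The controller is receding-horizon quadratic tracking with box constraints,
solved with `scipy.optimize.lsq_linear` (BVLS — exact, deterministic, no
tolerance knobs to drift). Defaults: prediction horizon 30 beats, 6 free
moves with the last held to the end of the horizon (move blocking), unit
output weights, move-increment weight 1.0, no effort weight. Holding the
tail input is what kills the steady-state offset a short unblocked horizon
exhibits — with it, tracking error at beat 100 is below 10⁻⁸ relative across
seeds, and the QP stays small (36 variables). Pinned components
(`u_min = u_max`) are eliminated before the solve, so a fully pinned box
degenerates to a constant controller. The state estimate is the model
replica driven by the applied inputs — exact here because the demo is
mismatch-free; a real deployment would substitute an observer. On solver
failure the previous input is held, clipped to the box.

The power meter passes `u` and `ym` through unchanged on its second port
pair and accumulates `60/HR · (f₁pw₁ + f₂pw₂ + f₃pw₃)` per beat, skipping
beats with zero heart rate. The knob testbench evaluates a threshold rule on
the observed output and emits a payload that scales the plant's input
sensitivity; the plant reads its knob port without registering it for change
detection, falling back to gain 1.0 when the port or file is absent, so the
knob can never pace or deadlock the loop.

`sequential_reference_sim` is the oracle: the same plant and controller
objects stepped alternately in one process. Beat *t* consumes the previous
input (initially zero), emits `ym_t`, and the controller answers `u_t`.
Because the protocol is lossless, ordered, and full-precision, the file
study, the mediated pair, and the oracle agree exactly (`max |Δ| = 0`), and
the tests assert exactly that.

## What the synthetic conditions do and do not show

The generated plants are linear, stable, noise-free, and mismatch-free
(controller model = plant), and the demo reports per-beat averages rather
than intra-beat pressure waveforms. Passing tests therefore demonstrate the
*orchestration* claims — synchronization correctness, race tolerance,
execution-mode equivalence, isolation — and that the controller design is
sound on the stated model class. They do not validate control performance
on pulsatile or nonlinear physiology, under measurement noise, or with
plant-model mismatch; those need a richer PM plugged into the same ports.

## Problem sizes and numerical choices

The standard demonstration is 200 beats (the loop settles within ~20); the
steady-state check uses 50 systems × 500 beats against the closed form at
1e-9; tracking uses 10 systems × 100 beats at a 1 % band; power-meter and
fault runs use 60 and 100 beats. Node poll delay is 0.01 s everywhere;
mediated tests poll at 0.01 s with a 60 s no-progress deadline. Fault
injection uses rate 0.15 per poll. Trajectory CSVs store `repr` floats, so
reading a log back is bit-exact. Equality comparisons between execution
modes use exact `==` on purpose: any nondeterminism is a bug, not noise.

## Known limitations

- One mediator per loop; no multi-hop or peer-to-peer topologies.
- Process control is spawn/terminate only — no scheduling, retries, or
  resource limits; a node whose peer exits mid-handshake waits until
  `stop`.
- Launchers are configured for `.py`/`.sh`; other recognized source kinds
  (Octave/Matlab, C++, Verilog) parse and plan but need a launcher entry or
  a container.
- The mediator's per-file locks live in one server process; running several
  worker processes would need cross-process locking.
- Windows directory aliasing (junction points) is untested here; the layout
  abstraction is "two paths, one directory" and would take a `mklink`-based
  link function.
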