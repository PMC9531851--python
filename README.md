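# cosimloop

Closed-loop co-simulation of physiological models and their controllers.

Designing a closed-loop neuromodulation system — say, vagus nerve
stimulation that regulates heart rate and blood pressure — requires running
a *controller* against a *physiological model* (PM) in a feedback loop, with
the two programs possibly written in different languages, packaged as
containers, or running at different institutions. Mainstream workflow
engines assume DAGs and re-launch a process per task, which makes a loop
with thousands of iterations impractical. `cosimloop` instead keeps every
node running and synchronizes them through a deliberately minimal file
protocol, so the same node code runs unchanged whether the loop is local,
containerized, or split across sites.

## What's inside

- **`cosimloop.protocol`** — the channel discipline. Each message is a text
  file `[simtime,v1,...,vn]`: a simulation timestamp plus a flat vector.
  Nodes poll their input files (sleeping `delay` seconds, default 0.01 s),
  proceed when content changes, tolerate the transient zero-byte state a
  mid-rewrite reader can observe, and advance the shared clock by a
  `delta ≥ 0` on each write. `concore.maxtime` sidecar files set the
  horizon.
- **`cosimloop.graph`** — cyclic workflow definitions in GraphML (as emitted
  by common graphical editors). Node labels declare what runs
  (`CZ:controller.py`, a prebuilt image `CZ:image`, or a null node `IN:`
  exposing a channel to the outside); uniquely labeled edges become shared
  channel directories; ports are numbered deterministically in document
  order.
- **`cosimloop.study`** — materializes a graph into a runnable *study*:
  per-node directories whose `in<k>`/`out<k>` ports are symlinked to shared
  edge directories, plus the lifecycle verbs `run`, `stop`, `clear`,
  `maxtime`, `debug`, and generation of an equivalent container plan (named
  volumes per edge, read-only in-port mounts).
- **`cosimloop.mediator`** — distributed loops. A small multi-tenant HTTP
  server stores each workflow's channel files under
  `sanitize(dirname)_apikey` with per-file locking; node-side *wrappers*
  bridge the local file protocol to `POST /ctl` and `/pm` exchanges, so a
  loop split across two machines reproduces the local trajectory
  byte-for-byte.
- **`cosimloop.demo`** — the cardiac use case: a discrete state-space plant
  `x(t+1) = A x(t) + B u(t)`, `ym(t+1) = C x(t) + D u(t)` mapping a
  six-element stimulation vector (three sites × frequency, pulse width) to
  (MAP, HR); a box-constrained MPC tracker solved as bounded least squares;
  a power meter accumulating `Σ 60/HR · (f₁pw₁ + f₂pw₂ + f₃pw₃)`; knob
  testbench nodes; and a sequential in-process reference simulator used as
  ground truth.

## Worked example

Build and run the two-node demo loop (controller `CZ` and plant `PZ`
exchanging `u` and `ym` through edge directories `VCY`/`VPY`), then compare
against the in-process reference:

```python
import tempfile
from cosimloop.demo import (MPCConfig, make_demo_system, make_demo_study,
                            run_to_completion, read_trajectory,
                            sequential_reference_sim, trajectory_max_diff)

with tempfile.TemporaryDirectory() as td:
    layout = make_demo_study(td, "basic", seed=0, beats=200)
    run_to_completion(layout, nodes=["CZ", "PZ"])
    traj = read_trajectory(layout, "CZ")           # t, u (6 cols), MAP, HR

oracle = sequential_reference_sim(make_demo_system(0), MPCConfig(), 200)
print(traj["ym"][0], traj["ym"][4].round(2), traj["ym"][-1])
print("max |file run - reference| =", trajectory_max_diff(traj, oracle))
```

prints

```
[0. 0.] [106.07 375.29] [110.4 374.5]
max |file run - reference| = 0.0
```

Beat 1 emits zeros (zero initial state and stimulation); by beat 5 the
controller has driven the outputs near the target; by beat 200 the loop sits
on the setpoint of 110.4 mmHg mean arterial pressure and 374.5 bpm heart
rate, with every stimulation value inside its 0–50 Hz / 0–1 ms box. The
file-based run is *exactly* — to the last bit — the reference trajectory:
the protocol transports full-precision text and the computation order is
identical.

The same loop can be driven from the shell:

```sh
cosimloop demo-make work --topology basic --seed 0 --beats 200
cosimloop run work/basic        # later: cosimloop stop work/basic
cosimloop summary work/sdir_basic/basic.graphml
```

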