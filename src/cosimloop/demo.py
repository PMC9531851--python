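"""Cardiac closed-loop demonstration: plant, controller, and testbench nodes.

The physiological model (PM) is a discrete-time linear state-space system

    x(t+1)  = A x(t) + B u(t)
    ym(t+1) = C x(t) + D u(t)

driven once per simulated heartbeat.  The stimulation vector ``u`` has six
elements -- three stimulation sites (vagal, sympathetic, baroreceptive), each
a (frequency, pulse width) pair -- and the output ``ym`` has two: mean
arterial pressure (MAP, mmHg) and heart rate (HR, bpm), in that order (the
power-meter convention ``period = 60 / ym[1]`` fixes HR at index 1).  The
controller is a finite-horizon model-predictive tracker with box constraints
on the stimulation, solved as a bounded linear least-squares problem.

Because no canonical plant matrices exist, :func:`generate_stable_system`
draws random stable systems (spectral radius 0.9) whose steady-state gain has
rank 2, so any two-output setpoint is reachable; :func:`make_demo_system`
additionally rescales the output map so the demo setpoint (110.4 mmHg,
374.5 bpm -- a rat's) sits exactly at the middle of the stimulation box.

:func:`sequential_reference_sim` runs the identical plant/controller
computations in-process with no file I/O; it is the ground truth that the
file-based, containerized and mediated executions must reproduce
element-for-element.

Loop start-up convention: the PM initiates (its first read fires on the
initial ``u`` string) and the controller is strictly reactive, so exactly one
node seeds the loop and the trajectory does not depend on process scheduling.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .graph import EdgeSpec, NodeSpec, WorkflowGraph, write_graphml
from .protocol import ConfigError, NodeIO, PORTS_FILENAME, read_raw, write_raw
from .study import StudyLayout, build_study, set_maxtime

__all__ = [
    "DemoError",
    "INIT_U",
    "INIT_YM",
    "U_MIN",
    "U_MAX",
    "SETPOINT",
    "LinearCardiacPM",
    "pm_step",
    "steady_state",
    "generate_stable_system",
    "make_demo_system",
    "MPCConfig",
    "MPCController",
    "mpc_control_step",
    "EnergyAccumulator",
    "power_meter_step",
    "knob_testbench_step",
    "sequential_reference_sim",
    "stimulation_energy",
    "build_demo_graph",
    "make_demo_study",
    "run_to_completion",
    "read_trajectory",
    "trajectory_max_diff",
    "run_local_demo",
    "run_distributed_demo",
    "run_controller_node",
    "run_pm_node",
    "run_power_meter_node",
    "run_knob_node",
    "run_wrapper_node",
]


class DemoError(RuntimeError):
    pass


#: Initial channel payloads at simulation time 0 (both vectors all-zero).
INIT_U = "[0.0,0.0,0.0,0.0,0.0,0.0,0.0]"
INIT_YM = "[0.0,0.0,0.0]"

#: Stimulation box: per site, frequency 0-50 Hz and pulse width 0-1 ms.
U_MIN = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
U_MAX = (50.0, 1.0, 50.0, 1.0, 50.0, 1.0)

#: Default target: (MAP mmHg, HR bpm) for a rat.
SETPOINT = (110.4, 374.5)


# ---------------------------------------------------------------------------
# Plant


@dataclass
class LinearCardiacPM:
    """Discrete state-space plant mapping stimulation to (MAP, HR)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.A, self.B = np.asarray(self.A, float), np.asarray(self.B, float)
        self.C, self.D = np.asarray(self.C, float), np.asarray(self.D, float)
        self.x = np.asarray(self.x, float).reshape(-1)
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape[0] != n or self.C.shape[1] != n \
                or self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise DemoError("inconsistent state-space dimensions")

    def copy(self) -> "LinearCardiacPM":
        return LinearCardiacPM(self.A.copy(), self.B.copy(), self.C.copy(),
                               self.D.copy(), self.x.copy())

    def step(self, u: Sequence[float], gain: float = 1.0) -> np.ndarray:
        """One heartbeat: emit C x + D u' from the pre-update state, then
        advance x := A x + B u', with u' = gain * u (``gain`` is the optional
        testbench knob scaling stimulation sensitivity)."""
        u = gain * np.asarray(u, float).reshape(-1)
        if u.shape[0] != self.B.shape[1]:
            raise DemoError(f"input length {u.shape[0]} != {self.B.shape[1]}")
        ym = self.C @ self.x + self.D @ u
        self.x = self.A @ self.x + self.B @ u
        return ym

    def dc_gain(self) -> np.ndarray:
        """Steady-state gain C (I - A)^-1 B + D (requires a stable A)."""
        n = self.A.shape[0]
        if max(abs(np.linalg.eigvals(self.A))) >= 1.0:
            raise DemoError("unstable A: no steady state")
        return self.C @ np.linalg.solve(np.eye(n) - self.A, self.B) + self.D

    def to_config(self) -> dict:
        return {"A": self.A.tolist(), "B": self.B.tolist(),
                "C": self.C.tolist(), "D": self.D.tolist(), "x0": self.x.tolist()}

    @classmethod
    def from_config(cls, cfg: Mapping) -> "LinearCardiacPM":
        return cls(np.array(cfg["A"]), np.array(cfg["B"]),
                   np.array(cfg["C"]), np.array(cfg["D"]), np.array(cfg["x0"]))


def pm_step(model: LinearCardiacPM, u: Sequence[float]) -> np.ndarray:
    """One plant step (functional form of :meth:`LinearCardiacPM.step`)."""
    return model.step(u)


def steady_state(model: LinearCardiacPM, u: Sequence[float]) -> np.ndarray:
    """Closed-form limit of the output under constant input ``u``."""
    return model.dc_gain() @ np.asarray(u, float).reshape(-1)


def generate_stable_system(seed: int, n: int = 8, n_inputs: int = 6,
                           n_outputs: int = 2, spectral_radius: float = 0.9,
                           max_tries: int = 100) -> LinearCardiacPM:
    """Draw a random stable system with full-rank steady-state gain.

    ``A`` is rescaled to the given spectral radius; candidates whose DC-gain
    matrix is rank-deficient (unreachable setpoints) are rejected and
    redrawn.  Deterministic per seed.
    """
    if n < 2:
        raise DemoError("state dimension must be at least 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        A = rng.normal(size=(n, n))
        radius = max(abs(np.linalg.eigvals(A)))
        A *= spectral_radius / radius
        B = rng.normal(size=(n, n_inputs))
        C = rng.normal(size=(n_outputs, n))
        D = 0.1 * rng.normal(size=(n_outputs, n_inputs))
        model = LinearCardiacPM(A, B, C, D, np.zeros(n))
        s = np.linalg.svd(model.dc_gain(), compute_uv=False)
        if s[-1] > 1e-9 * s[0]:
            return model
    raise DemoError(f"no rank-{n_outputs} DC gain in {max_tries} draws (seed {seed})")


def make_demo_system(seed: int, setpoint: Sequence[float] = SETPOINT,
                     u_min: Sequence[float] = U_MIN,
                     u_max: Sequence[float] = U_MAX) -> LinearCardiacPM:
    """A generated system rescaled so ``setpoint`` is exactly reachable.

    The output rows of C and D are scaled so that the middle of the
    stimulation box maps to the setpoint at steady state.
    """
    setpoint = np.asarray(setpoint, float)
    u_mid = (np.asarray(u_min, float) + np.asarray(u_max, float)) / 2.0
    attempt = 0
    while True:
        model = generate_stable_system((int(seed) * 1009 + attempt) % 2**31)
        y_mid = model.dc_gain() @ u_mid
        if np.all(np.abs(y_mid) > 1e-6):
            scale = setpoint / y_mid
            model.C = scale[:, None] * model.C
            model.D = scale[:, None] * model.D
            return model
        attempt += 1
        if attempt > 50:
            raise DemoError("could not scale a system to the setpoint")


# ---------------------------------------------------------------------------
# Controller


@dataclass
class MPCConfig:
    """Finite-horizon quadratic tracking with box-constrained stimulation.

    ``output_weight`` weights the squared tracking error per output,
    ``move_weight`` penalizes input increments (regularizes without biasing
    the steady state), ``effort_weight`` penalizes input magnitude (off by
    default -- it trades tracking accuracy for stimulation amplitude).
    Inputs are move-blocked: ``control_horizon`` free moves, after which the
    input is held for the rest of the prediction horizon.  Holding the tail
    input both shrinks the optimization and kills the steady-state offset a
    short unblocked horizon would leave.
    """

    horizon: int = 30
    control_horizon: int = 6
    output_weight: tuple = (1.0, 1.0)
    effort_weight: float = 0.0
    move_weight: float = 1.0
    u_min: tuple = U_MIN
    u_max: tuple = U_MAX
    setpoint: tuple = SETPOINT

    def __post_init__(self) -> None:
        if self.horizon < 1 or not 1 <= self.control_horizon <= self.horizon:
            raise ConfigError("need 1 <= control_horizon <= horizon")
        if np.any(np.asarray(self.u_min) > np.asarray(self.u_max)):
            raise ConfigError("infeasible box: u_min > u_max")
        if np.any(np.asarray(self.output_weight) < 0) or self.effort_weight < 0 \
                or self.move_weight < 0:
            raise ConfigError("weights must be non-negative")


def _prediction_matrices(A, B, C, D, N):
    """Stacked output map: y_{0..N-1} = Phi x0 + Gamma [u_0;...;u_{N-1}],
    with y_k = C x_k + D u_k (the plant's output-before-update convention)."""
    n, m, p = A.shape[0], B.shape[1], C.shape[0]
    powers = [np.eye(n)]
    for _ in range(N - 1):
        powers.append(A @ powers[-1])
    Phi = np.zeros((p * N, n))
    Gamma = np.zeros((p * N, m * N))
    for k in range(N):
        Phi[k * p:(k + 1) * p] = C @ powers[k]
        Gamma[k * p:(k + 1) * p, k * m:(k + 1) * m] = D
        for j in range(k):
            Gamma[k * p:(k + 1) * p, j * m:(j + 1) * m] = C @ powers[k - 1 - j] @ B
    return Phi, Gamma


def mpc_control_step(config: MPCConfig, model: LinearCardiacPM,
                     x_hat: np.ndarray, ym: Sequence[float],
                     u_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One receding-horizon move.

    Solves the box-constrained quadratic tracking problem over the model's
    predicted outputs, applies the first input of the optimal sequence, and
    advances the state estimate by the model recursion with that input (the
    demo is mismatch-free, so the replica *is* the estimator; the measured
    ``ym`` is accepted for interface completeness).  If the solver fails the
    previous input is held, clipped into the box.
    """
    A, B, C, D = model.A, model.B, model.C, model.D
    n, m, p = A.shape[0], B.shape[1], C.shape[0]
    N, Nc = config.horizon, config.control_horizon
    x_hat = np.asarray(x_hat, float).reshape(n)
    u_prev = np.asarray(u_prev, float).reshape(m)
    lb = np.tile(np.asarray(config.u_min, float), Nc)
    ub = np.tile(np.asarray(config.u_max, float), Nc)

    Phi, Gamma = _prediction_matrices(A, B, C, D, N)
    # Move blocking: u_k is a free variable for k < Nc, then held constant.
    block = np.zeros((m * N, m * Nc))
    for k in range(N):
        j = min(k, Nc - 1)
        block[k * m:(k + 1) * m, j * m:(j + 1) * m] = np.eye(m)
    Gamma = Gamma @ block

    wq = np.sqrt(np.tile(np.asarray(config.output_weight, float), N))
    rows = [wq[:, None] * Gamma]
    rhs = [wq * (np.tile(np.asarray(config.setpoint, float), N) - Phi @ x_hat)]

    ws = np.sqrt(config.move_weight)
    M = np.eye(m * Nc)
    for k in range(1, Nc):
        M[k * m:(k + 1) * m, (k - 1) * m:k * m] = -np.eye(m)
    b_move = np.zeros(m * Nc)
    b_move[:m] = u_prev
    rows.append(ws * M)
    rhs.append(ws * b_move)

    if config.effort_weight > 0:
        we = np.sqrt(config.effort_weight)
        rows.append(we * np.eye(m * Nc))
        rhs.append(np.zeros(m * Nc))

    A_ls = np.vstack(rows)
    b_ls = np.concatenate(rhs)

    # Pinned components (u_min == u_max) are eliminated before solving.
    free = ub > lb
    U = lb.copy()
    try:
        if free.any():
            b_red = b_ls - A_ls[:, ~free] @ U[~free]
            res = lsq_linear(A_ls[:, free], b_red, bounds=(lb[free], ub[free]),
                             method="bvls")
            if res.status < 0:
                raise DemoError(f"solver failed: {res.message}")
            U[free] = res.x
    except (DemoError, np.linalg.LinAlgError, ValueError):
        u = np.clip(u_prev, config.u_min, config.u_max)
        return u, A @ x_hat + B @ u
    u = np.clip(U[:m], config.u_min, config.u_max)
    return u, A @ x_hat + B @ u


class MPCController:
    """Stateful wrapper around :func:`mpc_control_step` (estimate + last move)."""

    def __init__(self, config: MPCConfig, model: LinearCardiacPM,
                 x0: Optional[np.ndarray] = None,
                 u0: Optional[np.ndarray] = None) -> None:
        self.config = config
        self.model = model.copy()
        self.x_hat = np.array(x0 if x0 is not None else model.x, float).reshape(-1)
        self.u_prev = np.array(
            u0 if u0 is not None else np.zeros(model.B.shape[1]), float)

    def step(self, ym: Sequence[float]) -> np.ndarray:
        u, self.x_hat = mpc_control_step(self.config, self.model,
                                         self.x_hat, ym, self.u_prev)
        self.u_prev = u
        return u


# ---------------------------------------------------------------------------
# Testbench tools


@dataclass
class EnergyAccumulator:
    """Cumulative stimulation energy in frequency x pulse-width x seconds."""

    energy: float = 0.0


def power_meter_step(u: Sequence[float], ym: Sequence[float],
                     acc: EnergyAccumulator) -> tuple[Sequence[float], Sequence[float], EnergyAccumulator]:
    """Pass (u, ym) through unchanged while accumulating stimulation energy.

    With a nonzero heart rate the beat period is 60/HR seconds and each
    site contributes frequency x pulse width x period; a zero heart rate
    accumulates nothing (no beat, no period).
    """
    hr = float(ym[1])
    if hr != 0:
        period = 60.0 / hr
        acc.energy += period * (u[0] * u[1] + u[2] * u[3] + u[4] * u[5])
    return u, ym, acc


def stimulation_energy(u_seq: np.ndarray, ym_seq: np.ndarray) -> float:
    """Independent trajectory-level energy: sum of 60/HR_t x sum_i f_i pw_i."""
    total = 0.0
    for u, ym in zip(np.asarray(u_seq, float), np.asarray(ym_seq, float)):
        if ym[1] != 0:
            total += (60.0 / ym[1]) * (u[0] * u[1] + u[2] * u[3] + u[4] * u[5])
    return total


_KNOB_OPS = {">": np.greater, "<": np.less, ">=": np.greater_equal,
             "<=": np.less_equal}


def knob_testbench_step(ym: Sequence[float], rule: Mapping) -> list[float]:
    """Evaluate a threshold rule on an observed output and pick a knob payload.

    ``rule`` has keys ``output`` (index into ym), ``op`` (one of > < >= <=),
    ``threshold``, and the two branch payloads ``if_true`` / ``if_false``.
    The testbench never paces the simulation; it only emits tuning values.
    """
    try:
        op = _KNOB_OPS[rule["op"]]
        idx = int(rule["output"])
        thr = float(rule["threshold"])
        if_true = [float(v) for v in rule["if_true"]]
        if_false = [float(v) for v in rule["if_false"]]
        value = float(ym[idx])
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"malformed knob rule {rule!r}: {exc}") from exc
    return if_true if op(value, thr) else if_false


# ---------------------------------------------------------------------------
# Sequential in-process reference


def sequential_reference_sim(model: LinearCardiacPM, config: MPCConfig,
                             beats: int, *, meter: bool = False,
                             knob_schedule: Optional[Callable[[int], float]] = None,
                             ) -> dict[str, np.ndarray]:
    """Ground-truth closed loop with no file I/O.

    Runs the identical plant and controller computations alternately in one
    process: beat t consumes the previous input (initially the zero vector),
    emits ym_t, then the controller responds with u_t.  Optionally threads
    the pair through the power meter, and/or scales plant sensitivity by
    ``knob_schedule(t)``.  Returns arrays t, u (beats x 6), ym (beats x 2)
    and cumulative energy.
    """
    if beats < 1:
        raise DemoError("beats must be >= 1")
    pm = model.copy()
    ctl = MPCController(config, pm)
    u = np.zeros(pm.B.shape[1])
    acc = EnergyAccumulator()
    ts, us, yms, energies = [], [], [], []
    for t in range(1, beats + 1):
        gain = knob_schedule(t) if knob_schedule is not None else 1.0
        ym = pm.step(u, gain=gain)
        if meter:
            power_meter_step(u, ym, acc)
        u = ctl.step(ym)
        ts.append(float(t))
        us.append(u.copy())
        yms.append(ym.copy())
        energies.append(acc.energy)
    return {"t": np.array(ts), "u": np.array(us), "ym": np.array(yms),
            "energy": np.array(energies)}


def trajectory_max_diff(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray],
                        keys: Sequence[str] = ("t", "u", "ym")) -> float:
    """Largest element-wise absolute difference across trajectory arrays."""
    worst = 0.0
    for k in keys:
        xa, xb = np.asarray(a[k], float), np.asarray(b[k], float)
        if xa.shape != xb.shape:
            return float("inf")
        if xa.size:
            worst = max(worst, float(np.max(np.abs(xa - xb))))
    return worst


# ---------------------------------------------------------------------------
# Demo topologies and study construction

_NODE_SCRIPTS = {
    "controller_node.py": "from cosimloop.demo import run_controller_node\n\nrun_controller_node()\n",
    "pm_node.py": "from cosimloop.demo import run_pm_node\n\nrun_pm_node()\n",
    "powermeter_node.py": "from cosimloop.demo import run_power_meter_node\n\nrun_power_meter_node()\n",
    "knob_node.py": "from cosimloop.demo import run_knob_node\n\nrun_knob_node()\n",
    "wrapper_node.py": "from cosimloop.demo import run_wrapper_node\n\nrun_wrapper_node()\n",
}

_TOPOLOGIES: dict[str, tuple[list[str], list[tuple[str, str, str]]]] = {
    # label list, (edge label, tail, head) list -- document order fixes ports
    "basic": (
        ["CZ:controller_node.py", "PZ:pm_node.py"],
        [("VCY", "CZ", "PZ"), ("VPY", "PZ", "CZ")],
    ),
    "meter": (
        ["CZ:controller_node.py", "XZ:powermeter_node.py", "PZ:pm_node.py"],
        [("VC", "CZ", "XZ"), ("VXP", "XZ", "PZ"),
         ("VP", "PZ", "XZ"), ("VXC", "XZ", "CZ")],
    ),
    "null": (
        ["CZ:controller_node.py", "PZ:pm_node.py", "IN:", "OUT:"],
        [("VCZ", "CZ", "PZ"), ("VOUT", "CZ", "OUT"),
         ("VPZ", "PZ", "CZ"), ("VIN", "IN", "CZ")],
    ),
    "knob": (
        ["CZ:controller_node.py", "PZ:pm_node.py", "OZ:knob_node.py"],
        [("VCY", "CZ", "PZ"), ("VPY", "PZ", "CZ"),
         ("VOBS", "PZ", "OZ"), ("KNOB", "OZ", "PZ")],
    ),
    # knob in-port present on the PM but nothing ever writes it
    "knob_null": (
        ["CZ:controller_node.py", "PZ:pm_node.py", "KN:"],
        [("VCY", "CZ", "PZ"), ("VPY", "PZ", "CZ"), ("KNOB", "KN", "PZ")],
    ),
    "ctl_site": (
        ["CZ:controller_node.py", "CW:wrapper_node.py"],
        [("VC", "CZ", "CW"), ("VY", "CW", "CZ")],
    ),
    "pm_site": (
        ["PZ:pm_node.py", "PW:wrapper_node.py"],
        [("VP", "PZ", "PW"), ("VU", "PW", "PZ")],
    ),
}


def build_demo_graph(topology: str, name: Optional[str] = None) -> WorkflowGraph:
    """The demonstration workflow graphs (feedback pair, power meter
    insertion, null-node I/O exposure, knob testbench, wrapper sites)."""
    if topology not in _TOPOLOGIES:
        raise DemoError(f"unknown topology {topology!r}; "
                        f"choose from {sorted(_TOPOLOGIES)}")
    labels, edge_triples = _TOPOLOGIES[topology]
    nodes = []
    for lbl in labels:
        nm, _, rest = lbl.partition(":")
        kind = "null" if not rest else "source"
        nodes.append(NodeSpec(nm, kind, rest or None))
    edges = [EdgeSpec(lbl, tail, head) for lbl, tail, head in edge_triples]
    return WorkflowGraph(name or topology, nodes, edges)


_DEFAULT_METER_PORTS = {"u_in": "VC", "u_out": "VXP", "ym_in": "VP", "ym_out": "VXC"}
_DEFAULT_KNOB_RULE = {"output": 0, "op": ">", "threshold": 100.0,
                      "if_true": [1.0], "if_false": [1.0]}


def make_demo_study(dest: Path | str, topology: str = "basic", *, seed: int = 0,
                    beats: int = 200, delay: float = 0.01,
                    fault_rate: float = 0.0, fault_seed: int = 0,
                    system: Optional[LinearCardiacPM] = None,
                    config: Optional[MPCConfig] = None,
                    knob_rule: Optional[Mapping] = None,
                    wrapper: Optional[Mapping] = None,
                    name: Optional[str] = None) -> StudyLayout:
    """Write a self-contained source directory and build the study from it.

    The source directory gets the node scripts, the workflow GraphML, and a
    ``model.json`` carrying the plant matrices, controller configuration and
    runtime settings every node reads at boot.  The horizon ``beats`` is
    broadcast to all edge directories.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    g = build_demo_graph(topology, name=name)
    sdir = dest / f"sdir_{g.name}"
    sdir.mkdir(exist_ok=True)

    model = system if system is not None else make_demo_system(seed)
    cfg_obj = config if config is not None else MPCConfig()
    cfg = {
        "system": model.to_config(),
        "mpc": asdict(cfg_obj),
        "init": {"u": INIT_U, "ym": INIT_YM},
        "runtime": {"delay": delay, "fault_rate": fault_rate,
                    "fault_seed": fault_seed},
        "beats": beats,
        "meter": _DEFAULT_METER_PORTS,
        "knob_rule": dict(knob_rule) if knob_rule else dict(_DEFAULT_KNOB_RULE),
        "knob_init": "[0.0,1.0]",
        "passthrough": {"name": "x", "init": "[0.0,0.0]"},
    }
    if wrapper is not None:
        cfg["wrapper"] = dict(wrapper)
    (sdir / "model.json").write_text(json.dumps(cfg, indent=1))
    for n in g.nodes:
        if n.kind == "source":
            (sdir / n.source).write_text(_NODE_SCRIPTS[n.source])
    (sdir / f"{g.name}.graphml").write_text(write_graphml(g))

    layout = build_study(g, sdir, dest, delay=delay)
    set_maxtime(layout, beats)
    return layout


def run_to_completion(layout: StudyLayout, nodes: Optional[Sequence[str]] = None,
                      timeout: float = 300.0):
    """Run a study and block until the given nodes (default all) exit cleanly.

    Raises with the offending node's log if any process exits nonzero or the
    timeout lapses (remaining processes are stopped either way).
    """
    import time as _time

    from .study import LOG_FILENAME, run_study

    handle = run_study(layout)
    names = list(nodes) if nodes is not None else list(handle.procs)
    deadline = _time.monotonic() + timeout
    try:
        while True:
            rcs = {n: handle.procs[n].poll() for n in names}
            bad = {n: rc for n, rc in rcs.items() if rc not in (None, 0)}
            if bad:
                logs = {n: _tail(layout.node_dirs[n] / LOG_FILENAME) for n in bad}
                raise DemoError(f"nodes failed: {bad}; logs: {logs}")
            if all(rc == 0 for rc in rcs.values()):
                return handle
            if _time.monotonic() > deadline:
                alive = [n for n, rc in rcs.items() if rc is None]
                logs = {n: _tail(layout.node_dirs[n] / LOG_FILENAME) for n in alive}
                raise DemoError(f"timeout; still running: {alive}; logs: {logs}")
            _time.sleep(0.02)
    finally:
        handle.stop()


def _tail(path: Path, limit: int = 800) -> str:
    try:
        return path.read_text()[-limit:]
    except OSError:
        return "<no log>"


# ---------------------------------------------------------------------------
# Trajectory logs


class _TrajectoryLog:
    """Incremental CSV log: t, u1..u6, MAP, HR[, energy]."""

    def __init__(self, path: Path | str, energy: bool = False) -> None:
        self.energy = energy
        self.fh = open(path, "w")
        cols = ["t"] + [f"u{i}" for i in range(1, 7)] + ["MAP", "HR"]
        if energy:
            cols.append("energy")
        self.fh.write(",".join(cols) + "\n")
        self.fh.flush()

    def row(self, t: float, u: Sequence[float], ym: Sequence[float],
            energy: Optional[float] = None) -> None:
        vals = [t, *u, *ym] + ([energy] if self.energy else [])
        self.fh.write(",".join(repr(float(v)) for v in vals) + "\n")
        self.fh.flush()

    def close(self) -> None:
        self.fh.close()


def read_trajectory(layout: StudyLayout, node: str) -> dict[str, np.ndarray]:
    """Parse a node's trajectory log back into arrays (exact round-trip)."""
    path = layout.node_dirs[node] / "trajectory.csv"
    lines = path.read_text().strip().splitlines()
    header = lines[0].split(",")
    data = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    if data.size == 0:
        data = data.reshape(0, len(header))
    out = {"t": data[:, 0], "u": data[:, 1:7], "ym": data[:, 7:9]}
    if "energy" in header:
        out["energy"] = data[:, 9]
    return out


# ---------------------------------------------------------------------------
# Node programs (entry points run inside node directories)


def _node_setup(cwd: Path = Path(".")):
    cfg = json.loads((cwd / ".." / "src" / "model.json").read_text())
    reg = json.loads((cwd / PORTS_FILENAME).read_text())
    io = NodeIO.from_dir(cwd)
    rt = cfg.get("runtime", {})
    io.state.delay = float(rt.get("delay", io.state.delay))
    rate = float(rt.get("fault_rate", 0.0))
    if rate > 0:
        io.state.fault_rate = rate
        io.state.fault_seed = (int(rt.get("fault_seed", 0)) * 1000003
                               + zlib.crc32(reg["node"].encode())) % 2**31
    io.load_maxtime(default=float(cfg.get("beats", 300)))
    return cfg, io


def _write_stats(io: NodeIO, cwd: Path = Path(".")) -> None:
    (cwd / "runtime_stats.json").write_text(json.dumps(
        {"retrycount": io.state.retrycount, "simtime": io.state.simtime}))


def run_controller_node() -> None:
    """Reactive MPC controller: consume each new ym, answer with u (delta 0).

    If a second in/out port pair exists (the null-node topology), the raw
    payload arriving on in-port 2 is copied verbatim to out-port 2 each beat.
    """
    cfg, io = _node_setup()
    model = LinearCardiacPM.from_config(cfg["system"])
    mpc_cfg = MPCConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in cfg["mpc"].items()})
    ctl = MPCController(mpc_cfg, model)
    init_ym = cfg["init"]["ym"]
    passth = cfg.get("passthrough", {})
    log = _TrajectoryLog("trajectory.csv")
    try:
        while io.state.simtime < io.state.maxtime:
            while io.unchanged():
                ym = io.read(1, "ym", init_ym)
            u = ctl.step(np.asarray(ym))
            io.write(1, "u", u.tolist(), 0.0)
            log.row(io.state.simtime, u, ym)
            if io.has_in(2) and io.has_out(2) and passth:
                text = read_raw(io.in_bindings[2].directory, passth["name"])
                if text is None:
                    text = passth["init"]
                if text.strip():
                    write_raw(io.out_bindings[2].directory, passth["name"], text)
    finally:
        log.close()
        _write_stats(io)


def run_pm_node() -> None:
    """Plant node: initiates the loop, advances simulation time one beat per
    write.  An optional knob in-port scales stimulation sensitivity without
    pacing the loop (absent or unwritten knob = default gain 1)."""
    cfg, io = _node_setup()
    model = LinearCardiacPM.from_config(cfg["system"])
    init_u, init_ym = cfg["init"]["u"], cfg["init"]["ym"]
    knob_init = cfg.get("knob_init", "[0.0,1.0]")
    log = _TrajectoryLog("trajectory.csv")
    try:
        while io.state.simtime < io.state.maxtime:
            while io.unchanged():
                u = io.read(1, "u", init_u, fire_on_initial=True)
            gain = 1.0
            if io.has_in(2):
                knob = io.read(2, "knob", knob_init, register=False)
                if knob:
                    gain = float(knob[0])
            ym = model.step(np.asarray(u), gain=gain)
            io.write(1, "ym", ym.tolist(), 1.0)
            if io.has_out(2):
                io.write(2, "ym", ym.tolist(), 0.0)
            log.row(io.state.simtime, u, ym)
    finally:
        log.close()
        _write_stats(io)


def run_power_meter_node() -> None:
    """Pass-through instrumentation: forwards u and ym unchanged between its
    two port pairs while accumulating stimulation energy per beat."""
    cfg, io = _node_setup()
    ports = cfg.get("meter", _DEFAULT_METER_PORTS)
    init_u, init_ym = cfg["init"]["u"], cfg["init"]["ym"]
    acc = EnergyAccumulator()
    log = _TrajectoryLog("trajectory.csv", energy=True)
    try:
        while io.state.simtime < io.state.maxtime:
            while io.unchanged():
                u = io.read(ports["u_in"], "u", init_u, fire_on_initial=True)
            io.write(ports["u_out"], "u", u, 0.0)
            if io.state.simtime >= io.state.maxtime:
                break
            while io.unchanged():
                ym = io.read(ports["ym_in"], "ym", init_ym)
            io.write(ports["ym_out"], "ym", ym, 0.0)
            power_meter_step(u, ym, acc)
            log.row(io.state.simtime, u, ym, acc.energy)
    finally:
        log.close()
        _write_stats(io)


def run_knob_node() -> None:
    """Testbench observer: watch the plant output, emit the knob payload the
    threshold rule selects.  Never advances simulation time (delta 0)."""
    cfg, io = _node_setup()
    rule = cfg["knob_rule"]
    init_ym = cfg["init"]["ym"]
    try:
        while io.state.simtime < io.state.maxtime:
            while io.unchanged():
                ym = io.read(1, "ym", init_ym)
            io.write(1, "knob", knob_testbench_step(ym, rule), 0.0)
    finally:
        _write_stats(io)


def run_wrapper_node() -> None:
    """Bridge node: stands in for the remote peer, speaking the file protocol
    on its ports and HTTP to the mediator."""
    from .mediator import MediatorClient, run_wrapper

    cfg, io = _node_setup()
    w = cfg["wrapper"]
    client = MediatorClient(w["url"], w["apikey"])
    run_wrapper(
        in_dir=io.in_bindings[1].directory,
        out_dir=io.out_bindings[1].directory,
        upload_name=w["upload"],
        fetch_name=w["fetch"],
        initial_local=w["local_init"],
        initial_peer=w["peer_init"],
        client=client,
        dirname=w["dirname"],
        service=w["service"],
        poll=float(w.get("poll", 0.5)),
        deadline=float(w.get("deadline", 60.0)),
        default_maxtime=float(cfg.get("beats", 300)),
    )
    _write_stats(io)


# ---------------------------------------------------------------------------
# Orchestration helpers


def run_local_demo(dest: Path | str, topology: str = "basic", *, seed: int = 0,
                   beats: int = 200, timeout: float = 300.0,
                   **kw) -> tuple[StudyLayout, dict[str, np.ndarray]]:
    """Build and run a local file-based study; return the controller log."""
    layout = make_demo_study(dest, topology, seed=seed, beats=beats, **kw)
    waited = [n for n in ("CZ", "PZ") if n in layout.node_dirs]
    run_to_completion(layout, nodes=waited, timeout=timeout)
    return layout, read_trajectory(layout, "CZ")


def run_distributed_demo(dest: Path | str, *, mediator_url: str, apikey: str,
                         dirname: str = "demo", seed: int = 0, beats: int = 200,
                         poll: float = 0.01, deadline: float = 30.0,
                         delay: float = 0.01, timeout: float = 300.0,
                         ) -> dict[str, np.ndarray]:
    """Run the loop split across two wrapper-bridged studies.

    The controller site and the PM site each pair their node with a wrapper;
    the session is initialized with the standard zero payloads before any
    process starts.  Returns the controller-site trajectory, which must be
    element-wise identical to the local run's.
    """
    from .mediator import MediatorClient

    dest = Path(dest)
    system = make_demo_system(seed)
    common = dict(seed=seed, beats=beats, system=system, delay=delay)
    wrapper_common = {"url": mediator_url, "apikey": apikey, "dirname": dirname,
                      "poll": poll, "deadline": deadline}
    ctl_layout = make_demo_study(
        dest / "site1", "ctl_site",
        wrapper={**wrapper_common, "service": "pm", "fetch": "ym",
                 "upload": "u", "local_init": INIT_U, "peer_init": INIT_YM},
        **common)
    pm_layout = make_demo_study(
        dest / "site2", "pm_site",
        wrapper={**wrapper_common, "service": "ctl", "fetch": "u",
                 "upload": "ym", "local_init": INIT_YM, "peer_init": INIT_U},
        **common)

    MediatorClient(mediator_url, apikey).init(dirname, {"u": INIT_U, "ym": INIT_YM})

    from .study import run_study

    handles = [run_study(ctl_layout), run_study(pm_layout)]
    import time as _time
    deadline_t = _time.monotonic() + timeout
    try:
        procs = {f"{i}:{n}": p for i, h in enumerate(handles) for n, p in h.procs.items()}
        while True:
            rcs = {n: p.poll() for n, p in procs.items()}
            bad = {n: rc for n, rc in rcs.items() if rc not in (None, 0)}
            if bad:
                raise DemoError(f"distributed run failed: {bad}")
            if all(rc == 0 for rc in rcs.values()):
                break
            if _time.monotonic() > deadline_t:
                raise DemoError(f"distributed run timed out; alive: "
                                f"{[n for n, rc in rcs.items() if rc is None]}")
            _time.sleep(0.02)
    finally:
        for h in handles:
            h.stop()
    return read_trajectory(ctl_layout, "CZ")
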