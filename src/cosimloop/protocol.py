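"""File-based synchronization protocol between co-simulating nodes.

Concurrently running programs (a controller and a physiological model,
typically) exchange one-dimensional real vectors through small text files in
shared directories, one directory per channel.  Each payload carries a
simulation timestamp on the left::

    [5.0,110.4,374.5]

A node polls its input files, sleeping ``delay`` seconds between polls, and
proceeds when any input's content changes.  A file observed mid-rewrite has
zero bytes; readers treat that state (and a missing file at startup, for
which an initial string is supplied) as "keep polling".  Writers advance the
shared simulation clock by a non-negative ``delta`` on each write; a node's
main loop runs while its simulation time is below ``maxtime``, which is read
from ``concore.maxtime`` sidecar files placed in the channel directories.
"""

from __future__ import annotations

import json
import math
import os
import random
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DEFAULT_DELAY",
    "DEFAULT_MAXTIME",
    "MAXTIME_FILENAME",
    "ProtocolError",
    "MalformedMessage",
    "ConfigError",
    "Message",
    "PortBinding",
    "RuntimeState",
    "serialize_message",
    "parse_message",
    "read_port",
    "write_port",
    "write_raw",
    "read_raw",
    "unchanged",
    "load_maxtime",
    "NodeIO",
    "PORTS_FILENAME",
]

#: Poll sleep interval in seconds.  The workable range on commodity hardware
#: is roughly 0.005-0.02 s; the tuning heuristic is that the number of
#: zero-length re-reads (``retrycount``) should stay around 10 percent of the
#: number of simulation cycles.
DEFAULT_DELAY = 0.01

#: Simulation-time horizon used when no ``concore.maxtime`` file is present.
DEFAULT_MAXTIME = 300.0

#: Sidecar file naming the simulation-time horizon for a channel directory.
MAXTIME_FILENAME = "concore.maxtime"

#: Per-node port registry written by the study builder.
PORTS_FILENAME = "concore_ports.json"


class ProtocolError(RuntimeError):
    """A channel violated the protocol (corruption, length change, I/O)."""


class MalformedMessage(ProtocolError):
    """Text that is neither empty nor a well-formed bracketed vector."""


class ConfigError(RuntimeError):
    """Unusable node or channel configuration (e.g. bad maxtime file)."""


@dataclass(frozen=True)
class Message:
    """A simulation timestamp plus an ordered vector of reals."""

    simtime: float
    values: tuple[float, ...] = ()


def serialize_message(m: Message) -> str:
    """Encode a message as ``[simtime,v1,...,vn]``.

    Formatting uses ``repr`` of Python floats, which is deterministic and
    survives a parse round-trip at full double precision -- change detection
    compares file text byte-for-byte, so this matters.
    """
    fields = (m.simtime,) + tuple(m.values)
    for v in fields:
        if not math.isfinite(v):
            raise ProtocolError(f"cannot encode non-finite value {v!r}")
    return "[" + ",".join(repr(float(v)) for v in fields) + "]"


def parse_message(text: str) -> Optional[Message]:
    """Decode a serialized message.

    Returns ``None`` for zero-length (or all-whitespace) text: the file was
    caught mid-rewrite and the caller should keep polling.  Raises
    :class:`MalformedMessage` for anything else that is not a bracketed
    comma-separated list with at least the timestamp field.
    """
    stripped = text.strip()
    if not stripped:
        return None
    if not (stripped.startswith("[") and stripped.endswith("]")):
        raise MalformedMessage(f"not a bracketed vector: {stripped[:40]!r}")
    inner = stripped[1:-1].strip()
    if not inner:
        raise MalformedMessage("missing simulation timestamp")
    try:
        fields = [float(tok) for tok in inner.split(",")]
    except ValueError as exc:
        raise MalformedMessage(f"bad numeric field in {stripped[:40]!r}") from exc
    return Message(fields[0], tuple(fields[1:]))


@dataclass(frozen=True)
class PortBinding:
    """Where one port of one node reads or writes its files."""

    direction: str  # "in" | "out"
    index: int  # 1-based
    edge_label: str
    directory: Path
    filename: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("in", "out"):
            raise ValueError(f"direction must be 'in' or 'out', got {self.direction!r}")
        if self.index < 1:
            raise ValueError("port index is 1-based")


# Sentinel baseline meaning "whatever the first read returns counts as new".
_FIRE = object()


@dataclass
class RuntimeState:
    """Per-node protocol bookkeeping.

    ``simtime`` is non-decreasing: reads take the maximum of all observed
    timestamps, writes add ``delta >= 0``.  ``retrycount`` counts zero-length
    re-reads and is the knob-tuning signal for ``delay``.
    """

    simtime: float = 0.0
    delay: float = DEFAULT_DELAY
    maxtime: float = DEFAULT_MAXTIME
    retrycount: int = 0
    write_mode: str = "truncate"  # or "atomic"
    malformed_limit: int = 200
    # Fault injection: probability that a poll observes the transient
    # zero-byte state regardless of actual file content.  Used by tests and
    # the fault-tolerance demonstration; 0.0 disables it.
    fault_rate: float = 0.0
    fault_seed: Optional[int] = None
    # (port index, filename) -> last text accepted by unchanged(); the _FIRE
    # sentinel marks ports whose initial value counts as unread.
    last_content: dict = field(default_factory=dict)
    _pending: dict = field(default_factory=dict)
    _lengths: dict = field(default_factory=dict)
    _fault_rng: Optional[random.Random] = field(default=None, repr=False)

    def _inject_fault(self) -> bool:
        if self.fault_rate <= 0.0:
            return False
        if self._fault_rng is None:
            self._fault_rng = random.Random(self.fault_seed)
        return self._fault_rng.random() < self.fault_rate


def read_raw(directory: Path, filename: str) -> Optional[str]:
    """Current text of a channel file, or ``None`` if it does not exist."""
    try:
        return (Path(directory) / filename).read_text()
    except FileNotFoundError:
        return None


def write_raw(directory: Path, filename: str, text: str, mode: str = "truncate") -> None:
    """Write channel-file text verbatim (no restamping).

    ``truncate`` opens the file for writing in place, so a concurrent reader
    observes old content, zero bytes, or new content -- the three states the
    protocol tolerates.  ``atomic`` writes a temporary file and renames it,
    which removes the zero-byte window entirely.
    """
    path = Path(directory) / filename
    if mode == "atomic":
        tmp = path.with_name(path.name + ".tmp~")
        tmp.write_text(text)
        os.replace(tmp, path)
    elif mode == "truncate":
        with open(path, "w") as fh:
            fh.write(text)
    else:
        raise ConfigError(f"unknown write mode {mode!r}")


def read_port(
    state: RuntimeState,
    binding: PortBinding,
    filename: Optional[str] = None,
    initial: str = "",
    *,
    fire_on_initial: bool = False,
    register: bool = True,
) -> list[float]:
    """Read one input file, tolerating the transient zero-byte state.

    If the file does not exist yet, ``initial`` (a fully serialized message,
    which breaks the chicken-or-egg dependency between the two halves of a
    loop) is parsed instead.  Zero-length content increments ``retrycount``,
    sleeps ``delay`` and retries.  The message's timestamp raises
    ``state.simtime`` to the maximum of all observed times; its values are
    returned with the timestamp stripped.

    ``fire_on_initial`` controls whether the very first content seen on this
    port counts as new for :func:`unchanged` (the loop-initiating node sets
    it); by default a port only "changes" once its content differs from
    ``initial``.  ``register=False`` reads without participating in change
    detection at all -- used for optional, non-pacing inputs such as
    testbench knobs.
    """
    if binding.direction != "in":
        raise ProtocolError(f"read_port on out-port {binding.index}")
    name = filename or binding.filename
    if not name:
        raise ProtocolError("no filename for read_port")
    key = (binding.index, name)
    if register and key not in state.last_content:
        state.last_content[key] = _FIRE if fire_on_initial else initial

    malformed = 0
    while True:
        if state._inject_fault():
            text = ""
        else:
            raw = read_raw(binding.directory, name)
            text = initial if raw is None else raw
        if not text.strip():
            state.retrycount += 1
            time.sleep(state.delay)
            continue
        try:
            msg = parse_message(text)
        except MalformedMessage:
            malformed += 1
            if malformed > state.malformed_limit:
                raise ProtocolError(
                    f"persistent malformed content on in-port {binding.index} "
                    f"file {name!r} in {binding.directory}"
                )
            state.retrycount += 1
            time.sleep(state.delay)
            continue
        break
    assert msg is not None

    expected = state._lengths.get(key)
    if expected is None:
        state._lengths[key] = len(msg.values)
    elif expected != len(msg.values):
        raise ProtocolError(
            f"vector length changed on in-port {binding.index} file {name!r}: "
            f"expected {expected}, got {len(msg.values)}"
        )
    if register:
        state._pending[key] = text
    state.simtime = max(state.simtime, msg.simtime)
    return list(msg.values)


def write_port(
    state: RuntimeState,
    binding: PortBinding,
    filename: Optional[str] = None,
    values: Sequence[float] = (),
    delta: float = 0.0,
) -> None:
    """Advance simulation time by ``delta`` and write the stamped vector.

    The advanced time is what lands in the file, so a loop guarded by
    ``simtime < maxtime`` terminates after writing the horizon value.
    """
    if binding.direction != "out":
        raise ProtocolError(f"write_port on in-port {binding.index}")
    if delta < 0:
        raise ProtocolError("delta must be non-negative")
    name = filename or binding.filename
    if not name:
        raise ProtocolError("no filename for write_port")
    state.simtime += delta
    text = serialize_message(Message(state.simtime, tuple(float(v) for v in values)))
    try:
        write_raw(binding.directory, name, text, state.write_mode)
    except OSError as exc:
        raise ProtocolError(
            f"write failed on out-port {binding.index} file {name!r}: {exc}"
        ) from exc


def unchanged(state: RuntimeState) -> bool:
    """True while no registered input has produced new content.

    Compares the text most recently read on each registered port against the
    text accepted the last time this function returned False (or the port's
    initial).  While everything matches it sleeps ``delay`` and returns True,
    so ``while unchanged(): x = read(...)`` re-reads until any input differs;
    the loop then exits holding the fresh value.  Byte-identical rewrites do
    not count as change, which is why writers advance the timestamp.
    """
    changed = False
    for key, baseline in state.last_content.items():
        pending = state._pending.get(key)
        if pending is None:
            continue
        if baseline is _FIRE or pending != baseline:
            changed = True
            break
    if changed:
        for key, pending in state._pending.items():
            state.last_content[key] = pending
        return False
    time.sleep(state.delay)
    return True


def load_maxtime(
    state: RuntimeState,
    bindings: Iterable[PortBinding],
    default: float = DEFAULT_MAXTIME,
) -> float:
    """Largest horizon found in the bindings' ``concore.maxtime`` files.

    Falls back to ``default`` when no file exists.  Stores and returns the
    result; main loops run while ``simtime < maxtime``.
    """
    found: list[float] = []
    for binding in bindings:
        path = Path(binding.directory) / MAXTIME_FILENAME
        try:
            text = path.read_text()
        except FileNotFoundError:
            continue
        try:
            found.append(float(text.strip()))
        except ValueError as exc:
            raise ConfigError(f"unparsable {MAXTIME_FILENAME} in {binding.directory}") from exc
    state.maxtime = max(found) if found else float(default)
    return state.maxtime


# ---------------------------------------------------------------------------
# Node-side convenience wrapper


class NodeIO:
    """A node's view of its ports: registry plus runtime state.

    Ports may be addressed by 1-based index or by edge label (resolved
    through the ``iport``/``oport`` maps the study builder records in
    ``concore_ports.json``).
    """

    def __init__(
        self,
        in_bindings: Mapping[int, PortBinding],
        out_bindings: Mapping[int, PortBinding],
        iport: Optional[Mapping[str, int]] = None,
        oport: Optional[Mapping[str, int]] = None,
        state: Optional[RuntimeState] = None,
    ) -> None:
        self.in_bindings = dict(in_bindings)
        self.out_bindings = dict(out_bindings)
        self.iport = dict(iport or {})
        self.oport = dict(oport or {})
        self.state = state or RuntimeState()

    @classmethod
    def from_dir(cls, cwd: os.PathLike | str = ".") -> "NodeIO":
        """Bootstrap from a node directory.

        Prefers the port registry written by the study builder; otherwise
        scans for the native ``in<k>``/``out<k>`` layout or the rooted
        ``/inputs/input_<k>`` dialect used by hosted platforms.
        """
        cwd = Path(cwd)
        reg = cwd / PORTS_FILENAME
        if reg.exists():
            data = json.loads(reg.read_text())
            in_b = {
                int(k): PortBinding("in", int(k), lbl, (cwd / f"in{k}"))
                for k, lbl in data.get("in", {}).items()
            }
            out_b = {
                int(k): PortBinding("out", int(k), lbl, (cwd / f"out{k}"))
                for k, lbl in data.get("out", {}).items()
            }
            io = cls(in_b, out_b, data.get("iport"), data.get("oport"))
            if "delay" in data:
                io.state.delay = float(data["delay"])
            return io
        # No registry: scan directory layouts.
        in_b, out_b = {}, {}
        if Path("/inputs").is_dir() and any(Path("/inputs").glob("input_*")):
            for d in sorted(Path("/inputs").glob("input_*")):
                k = int(d.name.split("_")[1])
                in_b[k] = PortBinding("in", k, f"input_{k}", d)
            for d in sorted(Path("/outputs").glob("output_*")):
                k = int(d.name.split("_")[1])
                out_b[k] = PortBinding("out", k, f"output_{k}", d)
        else:
            for d in sorted(cwd.iterdir()) if cwd.is_dir() else []:
                if d.name.startswith("in") and d.name[2:].isdigit():
                    k = int(d.name[2:])
                    in_b[k] = PortBinding("in", k, d.name, d)
                elif d.name.startswith("out") and d.name[3:].isdigit():
                    k = int(d.name[3:])
                    out_b[k] = PortBinding("out", k, d.name, d)
        return cls(in_b, out_b)

    def _resolve(self, port: int | str, bindings: Mapping[int, PortBinding], label_map: Mapping[str, int]) -> PortBinding:
        if isinstance(port, str):
            if port not in label_map:
                raise ConfigError(f"unknown port label {port!r}")
            port = label_map[port]
        if port not in bindings:
            raise ConfigError(f"no port {port}")
        return bindings[port]

    def has_in(self, port: int | str) -> bool:
        return (self.iport.get(port) if isinstance(port, str) else port) in self.in_bindings

    def has_out(self, port: int | str) -> bool:
        return (self.oport.get(port) if isinstance(port, str) else port) in self.out_bindings

    def read(self, port: int | str, name: str, initial: str, **kw) -> list[float]:
        return read_port(self.state, self._resolve(port, self.in_bindings, self.iport), name, initial, **kw)

    def write(self, port: int | str, name: str, values: Sequence[float], delta: float = 0.0) -> None:
        write_port(self.state, self._resolve(port, self.out_bindings, self.oport), name, values, delta)

    def unchanged(self) -> bool:
        return unchanged(self.state)

    def load_maxtime(self, default: float = DEFAULT_MAXTIME) -> float:
        bindings = list(self.in_bindings.values()) + list(self.out_bindings.values())
        return load_maxtime(self.state, bindings, default)
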