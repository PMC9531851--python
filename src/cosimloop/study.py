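"""Materialize a workflow graph into a runnable study.

A *study* is the on-disk realization of a workflow: one directory per node,
one shared directory per edge, and the binding rule that a tail node's
``out<i>`` and the head node's ``in<j>`` are the same directory (realized
with symbolic links, exactly the "two paths, one directory" contract the
protocol needs).  The lifecycle verbs mirror the generated helper scripts of
the original tooling: run, stop, clear, maxtime, debug -- plus generation of
an equivalent container execution plan (named volumes for edges, read-only
in-port mounts).
"""

from __future__ import annotations

import json
import os
import shutil
import signal
import subprocess
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .graph import WorkflowGraph, assign_ports
from .protocol import MAXTIME_FILENAME, PORTS_FILENAME

__all__ = [
    "LAUNCHERS",
    "BuildError",
    "StudyError",
    "StudyLayout",
    "RunHandle",
    "ContainerPlan",
    "build_study",
    "load_study",
    "run_study",
    "stop_study",
    "clear_study",
    "set_maxtime",
    "debug_node",
    "generate_container_plan",
]

MARKER = ".study.json"
LOG_FILENAME = "concoreout.txt"
PID_FILENAME = "concorepid"

#: Launch command per recognized source extension (argv prefix; the source
#: filename is appended).  Extensions recognized by the graph parser but
#: absent here (compiled or licensed languages) fail run_study with a
#: configuration error before any process starts.
LAUNCHERS: dict[str, list[str]] = {
    ".py": [sys.executable],
    ".sh": ["sh"],
}


class BuildError(RuntimeError):
    pass


class StudyError(RuntimeError):
    pass


@dataclass
class StudyLayout:
    root: Path
    graph: WorkflowGraph
    node_dirs: dict[str, Path]
    edge_dirs: dict[str, Path]
    src_dir: Path
    ports: dict  # node -> PortMap

    def runnable_nodes(self) -> list[str]:
        return [n.name for n in self.graph.nodes if n.kind != "null"]


def build_study(g: WorkflowGraph, source_dir: os.PathLike | str,
                dest: os.PathLike | str = ".", *, delay: Optional[float] = None) -> StudyLayout:
    """Create the study directory tree for ``g`` under ``dest``.

    The study root is named after the workflow.  Rebuilding replaces a prior
    study; a pre-existing directory of the same name that is *not* a study is
    refused rather than clobbered.  Each source node's file must exist in
    ``source_dir`` (all of which is copied into the study's ``src``
    directory, so a study is self-contained).
    """
    if not g.nodes:
        raise BuildError("empty workflow graph")
    source_dir = Path(source_dir)
    root = Path(dest) / g.name
    if root.exists():
        if not (root / MARKER).exists():
            raise BuildError(f"{root} exists and is not a study; refusing to replace it")
        shutil.rmtree(root)

    for n in g.nodes:
        if n.kind == "source" and not (source_dir / n.source).exists():
            raise BuildError(f"source file {n.source!r} for node {n.name!r} "
                             f"not found in {source_dir}")

    root.mkdir(parents=True)
    src_dir = root / "src"
    src_dir.mkdir()
    for item in sorted(source_dir.iterdir()):
        if item.is_file():
            shutil.copy2(item, src_dir / item.name)

    ports = assign_ports(g)
    edge_dirs = {e.label: root / e.label for e in g.edges}
    for d in edge_dirs.values():
        d.mkdir()

    node_dirs: dict[str, Path] = {}
    for n in g.nodes:
        if n.kind == "null":
            continue  # null nodes expose channels only; no directory, no program
        nd = root / n.name
        nd.mkdir()
        node_dirs[n.name] = nd
        if n.kind == "source":
            shutil.copy2(source_dir / n.source, nd / n.source)
        pm = ports[n.name]
        for label, idx in pm.iport.items():
            _link(nd / f"in{idx}", edge_dirs[label])
        for label, idx in pm.oport.items():
            _link(nd / f"out{idx}", edge_dirs[label])
        reg = {
            "node": n.name,
            "iport": pm.iport,
            "oport": pm.oport,
            "in": {idx: lbl for lbl, idx in pm.iport.items()},
            "out": {idx: lbl for lbl, idx in pm.oport.items()},
        }
        if delay is not None:
            reg["delay"] = delay
        (nd / PORTS_FILENAME).write_text(json.dumps(reg, indent=1))

    layout = StudyLayout(root, g, node_dirs, edge_dirs, src_dir, ports)
    _save_marker(layout)
    return layout


def _link(link_path: Path, target: Path) -> None:
    """Bind two paths to one directory; symlink on POSIX, copy-free only."""
    rel = os.path.relpath(target, link_path.parent)
    os.symlink(rel, link_path, target_is_directory=True)


def _save_marker(layout: StudyLayout) -> None:
    from .graph import write_graphml

    data = {
        "graphml": write_graphml(layout.graph),
        "nodes": {k: str(v) for k, v in layout.node_dirs.items()},
        "edges": {k: str(v) for k, v in layout.edge_dirs.items()},
    }
    (layout.root / MARKER).write_text(json.dumps(data))


def load_study(root: os.PathLike | str) -> StudyLayout:
    """Reload a previously built study from its marker file."""
    from .graph import parse_graphml

    root = Path(root)
    marker = root / MARKER
    if not marker.exists():
        raise StudyError(f"{root} is not a study (missing {MARKER})")
    data = json.loads(marker.read_text())
    g = parse_graphml(data["graphml"], name=root.name)
    return StudyLayout(
        root,
        g,
        {k: Path(v) for k, v in data["nodes"].items()},
        {k: Path(v) for k, v in data["edges"].items()},
        root / "src",
        assign_ports(g),
    )


@dataclass
class RunHandle:
    """Aggregates the independent node processes of one run."""

    layout: StudyLayout
    procs: dict[str, subprocess.Popen] = field(default_factory=dict)

    def wait(self, timeout: Optional[float] = None, nodes: Optional[Sequence[str]] = None) -> None:
        """Block until the given nodes (default: all) exit."""
        names = list(nodes) if nodes is not None else list(self.procs)
        deadline = None if timeout is None else time.monotonic() + timeout
        while True:
            alive = [n for n in names if self.procs[n].poll() is None]
            if not alive:
                return
            if deadline is not None and time.monotonic() > deadline:
                raise TimeoutError(f"nodes still running: {alive}")
            time.sleep(0.02)

    def returncodes(self) -> dict[str, Optional[int]]:
        return {n: p.poll() for n, p in self.procs.items()}

    def stop(self) -> None:
        for p in self.procs.values():
            if p.poll() is None:
                p.terminate()
        deadline = time.monotonic() + 3.0
        for p in self.procs.values():
            while p.poll() is None and time.monotonic() < deadline:
                time.sleep(0.02)
            if p.poll() is None:
                p.kill()
                p.wait()


def _launch_command(source: str) -> list[str]:
    ext = os.path.splitext(source)[1].lower()
    if ext not in LAUNCHERS:
        raise StudyError(f"no launcher configured for extension {ext!r} ({source})")
    return LAUNCHERS[ext] + [source]


def run_study(layout: StudyLayout, nodes: Optional[Sequence[str]] = None) -> RunHandle:
    """Launch every runnable node as an independent process.

    Output goes to a per-node log; process ids are recorded for ``stop``.
    All launch commands are resolved *before* anything starts, so a missing
    launcher aborts cleanly.  A run without a prior ``clear`` warm-starts
    from whatever channel files the previous run left behind.
    """
    wanted = list(nodes) if nodes is not None else layout.runnable_nodes()
    commands: dict[str, list[str]] = {}
    for name in wanted:
        spec = layout.graph.node(name)
        if spec.kind == "prebuilt":
            if shutil.which("docker") is None:
                raise StudyError(
                    f"node {name!r} is a prebuilt image: container runtime required"
                )
            plan = generate_container_plan(layout.graph, layout.ports, source_dir=layout.src_dir)
            commands[name] = plan.run_argv(name)
        else:
            commands[name] = _launch_command(spec.source)

    handle = RunHandle(layout)
    for name, cmd in commands.items():
        nd = layout.node_dirs.get(name, layout.root)
        log = open(nd / LOG_FILENAME, "w")
        proc = subprocess.Popen(cmd, cwd=nd, stdout=log, stderr=subprocess.STDOUT)
        log.close()
        (nd / PID_FILENAME).write_text(str(proc.pid))
        handle.procs[name] = proc
    return handle


def stop_study(handle_or_layout) -> None:
    """Terminate a run's recorded processes; already-exited ones are fine."""
    if isinstance(handle_or_layout, RunHandle):
        handle_or_layout.stop()
        return
    layout: StudyLayout = handle_or_layout
    for nd in layout.node_dirs.values():
        pid_file = nd / PID_FILENAME
        if not pid_file.exists():
            continue
        try:
            pid = int(pid_file.read_text().strip())
            os.kill(pid, signal.SIGTERM)
        except (ValueError, ProcessLookupError, PermissionError):
            pass


def clear_study(layout: StudyLayout) -> None:
    """Erase channel payload files so the simulation restarts from scratch.

    The ``concore.maxtime`` horizon files are preserved: clearing data does
    not forget the configured simulation length.
    """
    for d in layout.edge_dirs.values():
        for f in d.iterdir():
            if f.name != MAXTIME_FILENAME and f.is_file():
                f.unlink()


def set_maxtime(layout: StudyLayout, t: float) -> None:
    """Broadcast the simulation-time horizon to every edge directory."""
    for d in layout.edge_dirs.values():
        (d / MAXTIME_FILENAME).write_text(repr(float(t)))


def debug_node(layout: StudyLayout, node: str) -> int:
    """Run one node in the foreground with live output (no log capture)."""
    spec = layout.graph.node(node)
    if spec.kind != "source":
        raise StudyError(f"node {node!r} has no launchable source")
    cmd = _launch_command(spec.source)
    return subprocess.call(cmd, cwd=layout.node_dirs[node])


# ---------------------------------------------------------------------------
# Container execution plans


@dataclass
class ContainerPlan:
    """Per-node images and volume mounts equivalent to the linked layout.

    Every edge label becomes a named volume; a node mounts its out-port
    volumes read-write at ``/out<k>`` and its in-port volumes read-only at
    ``/in<k>``.  Null nodes contribute volumes but no containers.
    """

    images: dict[str, str]  # node -> image name
    mounts: dict[str, list[tuple[str, str, bool]]]  # node -> (volume, path, ro)
    volumes: list[str]
    build_specs: dict[str, Optional[str]]  # node -> Dockerfile text (None: prebuilt)

    def run_argv(self, node: str) -> list[str]:
        argv = ["docker", "run", "--rm", f"--name={node}"]
        for vol, path, ro in self.mounts[node]:
            argv.append("-v")
            argv.append(f"{vol}:{path}:ro" if ro else f"{vol}:{path}")
        argv.append(self.images[node])
        return argv

    def run_script(self) -> str:
        lines = ["#!/bin/sh"]
        for node in self.images:
            lines.append(" ".join(self.run_argv(node)) + " &")
        return "\n".join(lines) + "\n"

    def build_script(self) -> str:
        lines = ["#!/bin/sh"]
        for node, spec in self.build_specs.items():
            if spec is None:
                continue  # prebuilt image: nothing to build
            lines.append(f"docker build -t {self.images[node]} -f {node}.Dockerfile src")
        return "\n".join(lines) + "\n"


_DEFAULT_DOCKERFILE = """\
FROM python:3-slim
RUN pip install --no-cache-dir numpy scipy networkx lxml click cosimloop || true
WORKDIR /app
COPY . /app
CMD ["python3", "{source}"]
"""


def generate_container_plan(g: WorkflowGraph, ports=None, *,
                            source_dir: Optional[os.PathLike | str] = None) -> ContainerPlan:
    """Derive the containerized execution plan for a validated graph.

    A per-node ``<stem>.Dockerfile`` in ``source_dir``, if present, overrides
    the default build spec (nodes needing extra dependencies supply one).
    """
    if ports is None:
        ports = assign_ports(g)
    images: dict[str, str] = {}
    mounts: dict[str, list[tuple[str, str, bool]]] = {}
    specs: dict[str, Optional[str]] = {}
    for n in g.nodes:
        if n.kind == "null":
            continue
        pm = ports[n.name]
        node_mounts = [(lbl, f"/out{idx}", False) for lbl, idx in pm.oport.items()]
        node_mounts += [(lbl, f"/in{idx}", True) for lbl, idx in pm.iport.items()]
        mounts[n.name] = node_mounts
        if n.kind == "prebuilt":
            images[n.name] = n.source
            specs[n.name] = None
        else:
            stem = os.path.splitext(n.source)[0]
            images[n.name] = f"docker-{stem}"
            override = None
            if source_dir is not None:
                cand = Path(source_dir) / f"{stem}.Dockerfile"
                if cand.exists():
                    override = cand.read_text()
            specs[n.name] = override or _DEFAULT_DOCKERFILE.format(source=n.source)
    return ContainerPlan(images, mounts, [e.label for e in g.edges], specs)
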