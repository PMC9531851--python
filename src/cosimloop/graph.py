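"""Cyclic workflow definitions: GraphML in, validated directed graphs out.

A workflow is a directed graph -- cycles are not only permitted but are the
point, since a feedback loop between a controller and a physiological model
is a 2-cycle.  Nodes are labeled ``NAME:source.ext`` (a program to launch),
``NAME:image`` (a prebuilt container image -- no recognized source
extension), or ``NAME:`` / bare ``NAME`` (a *null node*: no program, it
merely exposes a persistent channel to the outside).  Every edge carries a
label that is unique across the graph; edge labels become the names of the
shared channel directories.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import networkx as nx
from lxml import etree

__all__ = [
    "SOURCE_EXTENSIONS",
    "GraphValidationError",
    "MissingEdgeLabelError",
    "DuplicateEdgeLabelError",
    "DuplicateNodeNameError",
    "DanglingEdgeError",
    "IsolatedNodeError",
    "UnrecognizedExtensionError",
    "NodeSpec",
    "EdgeSpec",
    "WorkflowGraph",
    "PortMap",
    "parse_graphml",
    "load_workflow",
    "write_graphml",
    "assign_ports",
    "validate_loop_liveness",
]

#: Source-file extensions whose node programs the framework knows how to
#: launch or containerize.  Anything else after a node's colon that still
#: looks like a filename is rejected; a token with no extension is taken to
#: be a prebuilt container image reference.
SOURCE_EXTENSIONS = (".py", ".sh", ".m", ".cpp", ".v")


class GraphValidationError(ValueError):
    """A workflow definition violates a structural rule."""


class MissingEdgeLabelError(GraphValidationError):
    pass


class DuplicateEdgeLabelError(GraphValidationError):
    pass


class DuplicateNodeNameError(GraphValidationError):
    pass


class DanglingEdgeError(GraphValidationError):
    pass


class IsolatedNodeError(GraphValidationError):
    pass


class UnrecognizedExtensionError(GraphValidationError):
    pass


@dataclass(frozen=True)
class NodeSpec:
    """One workflow node: a launchable program, a prebuilt image, or null."""

    name: str
    kind: str  # "source" | "prebuilt" | "null"
    source: Optional[str] = None  # source filename or image reference

    @property
    def label(self) -> str:
        if self.kind == "null":
            return f"{self.name}:"
        return f"{self.name}:{self.source}"


@dataclass(frozen=True)
class EdgeSpec:
    """A directed channel from ``tail`` to ``head`` named ``label``."""

    label: str
    tail: str
    head: str


class PortMap(NamedTuple):
    iport: dict  # edge label -> 1-based in-port index
    oport: dict  # edge label -> 1-based out-port index


@dataclass
class WorkflowGraph:
    name: str
    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[EdgeSpec] = field(default_factory=list)

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(name=self.name)
        for n in self.nodes:
            g.add_node(n.name, kind=n.kind, source=n.source)
        for e in self.edges:
            g.add_edge(e.tail, e.head, label=e.label)
        return g


def _parse_node_label(label: str, extensions=SOURCE_EXTENSIONS) -> NodeSpec:
    label = label.strip()
    if ":" in label:
        name, _, rest = label.partition(":")
        name, rest = name.strip(), rest.strip()
    else:
        name, rest = label, ""  # bare name designates a null node
    if not name or any(sep in name for sep in ("/", "\\")) or name in (".", ".."):
        raise GraphValidationError(f"node name {name!r} is not directory-safe")
    if not rest:
        return NodeSpec(name, "null")
    ext = os.path.splitext(rest)[1]
    if ext:
        if ext.lower() not in extensions:
            raise UnrecognizedExtensionError(
                f"node {name!r}: unrecognized source extension {ext!r} in {rest!r}"
            )
        return NodeSpec(name, "source", rest)
    return NodeSpec(name, "prebuilt", rest)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _element_label(el) -> Optional[str]:
    """Display label of a GraphML node/edge element.

    Accepts both a plain ``label`` attribute and nested ``<data>`` text --
    including the style used by common graphical editors, where the label
    text sits inside a nested NodeLabel/EdgeLabel element.
    """
    attr = el.get("label")
    if attr and attr.strip():
        return attr.strip()
    for child in el:
        if _local(child.tag) != "data":
            continue
        text = " ".join("".join(child.itertext()).split())
        if text:
            return text
    return None


def parse_graphml(document: str | bytes, name: str = "workflow",
                  extensions=SOURCE_EXTENSIONS) -> WorkflowGraph:
    """Parse and validate a GraphML workflow definition.

    Raises a distinct :class:`GraphValidationError` subclass for each rule:
    missing edge label, duplicate edge label, duplicate node name, dangling
    edge endpoint, unrecognized source extension, non-null node with no
    edges.
    """
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)

    nodes: list[NodeSpec] = []
    id_to_name: dict[str, str] = {}
    edges: list[EdgeSpec] = []

    for el in root.iter():
        tag = _local(el.tag)
        if tag == "node":
            label = _element_label(el)
            if label is None:
                label = el.get("id", "")
            spec = _parse_node_label(label, extensions)
            if spec.name in (n.name for n in nodes):
                raise DuplicateNodeNameError(f"duplicate node name {spec.name!r}")
            nodes.append(spec)
            id_to_name[el.get("id", spec.name)] = spec.name
        elif tag == "edge":
            label = _element_label(el)
            src, dst = el.get("source"), el.get("target")
            if label is None:
                raise MissingEdgeLabelError(
                    f"edge {el.get('id') or f'{src}->{dst}'} has no label"
                )
            if any(e.label == label for e in edges):
                raise DuplicateEdgeLabelError(f"duplicate edge label {label!r}")
            for endpoint in (src, dst):
                if endpoint not in id_to_name:
                    raise DanglingEdgeError(
                        f"edge {label!r} references undeclared node {endpoint!r}"
                    )
            edges.append(EdgeSpec(label, id_to_name[src], id_to_name[dst]))

    g = WorkflowGraph(name, nodes, edges)
    touched = {e.tail for e in edges} | {e.head for e in edges}
    for n in nodes:
        if n.kind != "null" and n.name not in touched:
            raise IsolatedNodeError(f"node {n.name!r} has no edges")
    return g


def load_workflow(path: os.PathLike | str, extensions=SOURCE_EXTENSIONS) -> WorkflowGraph:
    """Parse a ``.graphml`` file; the workflow is named after the file."""
    from pathlib import Path

    p = Path(path)
    return parse_graphml(p.read_bytes(), name=p.stem, extensions=extensions)


def write_graphml(g: WorkflowGraph) -> str:
    """Serialize to normalized GraphML (plain ``label`` data entries)."""
    ns = "http://graphml.graphdrawing.org/xmlns"
    root = etree.Element(f"{{{ns}}}graphml", nsmap={None: ns})
    key = etree.SubElement(root, f"{{{ns}}}key")
    key.set("id", "label")
    key.set("for", "all")
    key.set("attr.name", "label")
    key.set("attr.type", "string")
    graph = etree.SubElement(root, f"{{{ns}}}graph", id=g.name, edgedefault="directed")
    ids = {}
    for i, n in enumerate(g.nodes):
        ids[n.name] = f"n{i}"
        el = etree.SubElement(graph, f"{{{ns}}}node", id=ids[n.name])
        d = etree.SubElement(el, f"{{{ns}}}data", key="label")
        d.text = n.label
    for i, e in enumerate(g.edges):
        el = etree.SubElement(
            graph, f"{{{ns}}}edge", id=f"e{i}", source=ids[e.tail], target=ids[e.head]
        )
        d = etree.SubElement(el, f"{{{ns}}}data", key="label")
        d.text = e.label
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def assign_ports(g: WorkflowGraph) -> dict[str, PortMap]:
    """Deterministic 1..k port numbering per node and direction.

    Ports are numbered in the stable order edges appear in the definition
    document, so two parses of the same file always agree.
    """
    ports = {n.name: PortMap({}, {}) for n in g.nodes}
    for e in g.edges:
        om = ports[e.tail].oport
        om[e.label] = len(om) + 1
        im = ports[e.head].iport
        im[e.label] = len(im) + 1
    return ports


def validate_loop_liveness(g: WorkflowGraph) -> list[str]:
    """Non-fatal sanity warnings about the feedback structure.

    Flags open-loop graphs (no cycle at all), null nodes that sit *inside* a
    cycle (they have no program to keep the loop alive), and nodes that are
    disconnected from every cycle.
    """
    warnings: list[str] = []
    nxg = g.to_networkx()
    cyclic: set[str] = set()
    for scc in nx.strongly_connected_components(nxg):
        if len(scc) > 1 or any(nxg.has_edge(v, v) for v in scc):
            cyclic |= set(scc)
    if not cyclic:
        warnings.append("open-loop workflow: the graph contains no cycle")
        return warnings
    null_names = {n.name for n in g.nodes if n.kind == "null"}
    for name in sorted(cyclic & null_names):
        warnings.append(f"null node {name!r} participates in a cycle but runs no program")
    connected = set(cyclic)
    for v in cyclic:
        connected |= nx.descendants(nxg, v)
        connected |= nx.ancestors(nxg, v)
    for name in sorted(set(g.node_names) - connected):
        warnings.append(f"node {name!r} is disconnected from every cycle")
    return warnings
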