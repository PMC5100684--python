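"""NML (XML) skeleton annotations, the NMX zip container, and the
innervation CSV.

The NML dialect covers ``things/thing/nodes/node`` and ``thing/edges/edge``
elements, a ``parameters/scale`` element carrying the nm voxel pitch, and a
``comments/comment`` section. Node attributes beyond id/x/y/z/radius are
passed through opaquely so foreign files round-trip. Coordinates are
1-based voxel indices on disk (the KNOSSOS convention) and 0-based in
memory; the writer/parser convert.

Synapses are serialized as 3-node, 2-edge things (pre -> cleft -> post)
whose nodes carry the comments ``pre``, ``cleft:<class>:<confidence>`` and
``post``. Soma outlines are things named ``soma_<owner>`` holding an
edge-free point set.

An NMX file is simply a zip archive of NML documents, one per annotation;
files named ``Neuron_id<N>.nmx`` carry the neuron id in metadata.
"""

from __future__ import annotations

import re
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .skeleton import DEFAULT_SCALE, Skeleton, SkeletonNode

__all__ = [
    "SynapseAnnotation", "SomaOutline", "Annotation", "NmxContainer",
    "InnervationTable", "CELL_TYPES",
    "parse_nml", "write_nml", "read_nmx", "write_nmx",
    "read_innervation_csv", "write_innervation_csv",
]

#: Valid cell-type labels for the innervation table.
CELL_TYPES = ("mitral", "IN1", "IN2", "IN3", "UPN", "LOC", "other")



@dataclass
class SynapseAnnotation:
    """A synapse annotated as three connected clicks: a node on the
    presynaptic neuron, one at the synaptic cleft, one on the postsynaptic
    neuron, with a user-defined class and an ordinal confidence."""

    pre_node: SkeletonNode
    cleft_node: SkeletonNode
    post_node: SkeletonNode
    class_label: str = "unclassified"
    confidence: int = 1
    thing_id: int = 0


@dataclass
class SomaOutline:
    points: np.ndarray  # (n, 3) voxel positions
    owner: int
    thing_id: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[0] < 4:
            raise ParameterError("a soma outline needs at least 4 points")


@dataclass
class Annotation:
    """Contents of one NML document."""

    skeletons: List[Skeleton] = field(default_factory=list)
    synapses: List[SynapseAnnotation] = field(default_factory=list)
    somata: List[SomaOutline] = field(default_factory=list)
    parameters: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def scale(self) -> Tuple[float, float, float]:
        s = self.parameters.get("scale")
        if not s:
            return DEFAULT_SCALE
        return (float(s["x"]), float(s["y"]), float(s["z"]))


@dataclass
class NmxContainer:
    entries: Dict[str, Annotation]
    source_name: str = ""
    neuron_id: Optional[int] = None


# ---------------------------------------------------------------------------
# NML writing (hand-assembled for byte-deterministic output)
# ---------------------------------------------------------------------------

def _fmt(v: float) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def _node_xml(node: SkeletonNode, out: List[str]) -> None:
    attrs = [f'id="{node.node_id}"',
             f'x={quoteattr(_fmt(node.position[0] + 1))}',
             f'y={quoteattr(_fmt(node.position[1] + 1))}',
             f'z={quoteattr(_fmt(node.position[2] + 1))}',
             f'radius={quoteattr(_fmt(node.radius))}']
    if node.time is not None:
        attrs.append(f'time={quoteattr(_fmt(node.time))}')
    for k in sorted(node.extra):
        attrs.append(f'{k}={quoteattr(str(node.extra[k]))}')
    out.append(f'      <node {" ".join(attrs)}/>')


def _thing_xml(thing_id: int, name: str, nodes: Sequence[SkeletonNode],
               edges: Sequence[Tuple[int, int]], out: List[str]) -> None:
    out.append(f'  <thing id="{thing_id}" name={quoteattr(name)}>')
    out.append('    <nodes>')
    for n in sorted(nodes, key=lambda n: n.node_id):
        _node_xml(n, out)
    out.append('    </nodes>')
    out.append('    <edges>')
    for a, b in sorted(edges):
        out.append(f'      <edge source="{a}" target="{b}"/>')
    out.append('    </edges>')
    out.append('  </thing>')


def write_nml(annotation: Annotation) -> str:
    """Serialize an annotation to NML text.

    Output is deterministic: things, nodes, edges, comments and pass-through
    attributes are emitted in sorted order, so the same annotation always
    yields byte-identical text. Coordinates are written 1-based.
    """
    out: List[str] = ['<?xml version="1.0" encoding="UTF-8"?>', "<things>"]
    params = dict(annotation.parameters)
    params.setdefault("scale", {"x": _fmt(DEFAULT_SCALE[0]),
                                "y": _fmt(DEFAULT_SCALE[1]),
                                "z": _fmt(DEFAULT_SCALE[2])})
    out.append("  <parameters>")
    for pname in sorted(params):
        attrs = " ".join(f'{k}={quoteattr(str(v))}'
                         for k, v in sorted(params[pname].items()))
        out.append(f"    <{pname} {attrs}/>")
    out.append("  </parameters>")

    comments: List[Tuple[int, str]] = []
    used_ids = [s.thing_id for s in annotation.skeletons]
    next_id = max(used_ids, default=0) + 1

    for skel in sorted(annotation.skeletons, key=lambda s: s.thing_id):
        _thing_xml(skel.thing_id, skel.name or f"skeleton_{skel.thing_id}",
                   list(skel.nodes.values()), sorted(skel.edges), out)
        for nid in sorted(skel.nodes):
            if skel.nodes[nid].comment:
                comments.append((nid, skel.nodes[nid].comment))

    for syn in annotation.synapses:
        tid = syn.thing_id or next_id
        next_id = max(next_id, tid) + 1
        trio = (syn.pre_node, syn.cleft_node, syn.post_node)
        edges = [(syn.pre_node.node_id, syn.cleft_node.node_id),
                 (syn.cleft_node.node_id, syn.post_node.node_id)]
        _thing_xml(tid, "synapse", trio, edges, out)
        comments.append((syn.pre_node.node_id, "pre"))
        comments.append((syn.cleft_node.node_id,
                         f"cleft:{syn.class_label}:{syn.confidence}"))
        comments.append((syn.post_node.node_id, "post"))

    for soma in annotation.somata:
        tid = soma.thing_id or next_id
        next_id = max(next_id, tid) + 1
        nodes = [SkeletonNode(i + 1, p) for i, p in enumerate(soma.points)]
        _thing_xml(tid, f"soma_{soma.owner}", nodes, [], out)

    out.append("  <comments>")
    for nid, text in sorted(comments):
        out.append(f'    <comment node="{nid}" content={quoteattr(text)}/>')
    out.append("  </comments>")
    out.append("</things>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# NML parsing
# ---------------------------------------------------------------------------

def _parse_thing_nodes(thing: ET.Element):
    nodes: Dict[int, SkeletonNode] = {}
    for ne in thing.iter("node"):
        attrs = dict(ne.attrib)
        try:
            nid = int(attrs.pop("id"))
            pos = (float(attrs.pop("x")) - 1, float(attrs.pop("y")) - 1,
                   float(attrs.pop("z")) - 1)
        except (KeyError, ValueError) as exc:
            raise FormatError(f"malformed node element: {ne.attrib}") from exc
        radius = float(attrs.pop("radius", 1.0))
        time = attrs.pop("time", None)
        node = SkeletonNode(nid, np.array(pos), radius,
                            float(time) if time is not None else None,
                            extra=attrs)
        if nid in nodes:
            raise FormatError(f"duplicate node id {nid}")
        nodes[nid] = node
    edges = []
    for ee in thing.iter("edge"):
        try:
            a, b = int(ee.attrib["source"]), int(ee.attrib["target"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"malformed edge element: {ee.attrib}") from exc
        for nid in (a, b):
            if nid not in nodes:
                raise FormatError(f"edge ({a}, {b}) references missing node {nid}")
        edges.append((a, b))
    return nodes, edges


_CLEFT_RE = re.compile(r"^cleft:(?P<cls>[^:]*):(?P<conf>-?\d+)$")


def parse_nml(document: str) -> Annotation:
    """Parse NML text into an :class:`Annotation`.

    Things named ``synapse`` (3 nodes, pre/cleft/post comments) become
    :class:`SynapseAnnotation`; things named ``soma_<owner>`` become
    :class:`SomaOutline`; everything else is a :class:`Skeleton`. Unknown
    node attributes are preserved for round-tripping.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc

    ann = Annotation()
    params = root.find("parameters")
    if params is not None:
        for el in params:
            ann.parameters[el.tag] = dict(el.attrib)

    comments: Dict[int, str] = {}
    celem = root.find("comments")
    if celem is not None:
        for ce in celem.iter("comment"):
            comments[int(ce.attrib["node"])] = ce.attrib.get("content", "")

    for thing in root.iter("thing"):
        tid = int(thing.attrib.get("id", 0))
        name = thing.attrib.get("name", "")
        nodes, edges = _parse_thing_nodes(thing)
        for nid, node in nodes.items():
            if nid in comments:
                node.comment = comments[nid]

        if name == "synapse" and len(nodes) == 3 and len(edges) == 2:
            by_comment = {}
            for node in nodes.values():
                c = node.comment or ""
                key = "cleft" if c.startswith("cleft:") else c
                by_comment[key] = node
            m = _CLEFT_RE.match(by_comment.get("cleft", SkeletonNode(0, (0, 0, 0))).comment or "")
            if {"pre", "cleft", "post"} <= set(by_comment) and m:
                ann.synapses.append(SynapseAnnotation(
                    pre_node=by_comment["pre"],
                    cleft_node=by_comment["cleft"],
                    post_node=by_comment["post"],
                    class_label=m.group("cls"),
                    confidence=int(m.group("conf")),
                    thing_id=tid))
                continue
        m = re.match(r"^soma_(\d+)$", name)
        if m and not edges:
            pts = np.array([nodes[i].position for i in sorted(nodes)])
            ann.somata.append(SomaOutline(pts, owner=int(m.group(1)),
                                          thing_id=tid))
            continue
        skel = Skeleton(thing_id=tid, name=name)
        skel.nodes = nodes
        for a, b in edges:
            skel.add_edge(a, b)
        ann.skeletons.append(skel)
    return ann


# ---------------------------------------------------------------------------
# NMX container
# ---------------------------------------------------------------------------

_NEURON_ID_RE = re.compile(r"Neuron_id(\d+)", re.IGNORECASE)


def write_nmx(annotations: Union[Dict[str, Annotation], Sequence[Annotation]],
              path: Union[str, Path]) -> None:
    """Write annotations into an NMX zip container, one NML per entry.

    A list is given entry names ``annotation_<i>.nml``; timestamps are
    fixed so identical content yields identical archives.
    """
    if not isinstance(annotations, dict):
        annotations = {f"annotation_{i}.nml": a
                       for i, a in enumerate(annotations)}
    if not annotations:
        raise ParameterError("an NMX container needs at least one entry")
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(annotations):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, write_nml(annotations[name]))


def read_nmx(path: Union[str, Path]) -> NmxContainer:
    """Read an NMX container; every archived NML is parsed independently."""
    path = Path(path)
    if not zipfile.is_zipfile(path):
        raise FormatError(f"{path} is not a zip archive")
    entries: Dict[str, Annotation] = {}
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            try:
                entries[name] = parse_nml(zf.read(name).decode("utf-8"))
            except FormatError as exc:
                raise FormatError(f"entry {name!r}: {exc}") from exc
    m = _NEURON_ID_RE.search(path.name)
    return NmxContainer(entries=entries, source_name=path.name,
                        neuron_id=int(m.group(1)) if m else None)


# ---------------------------------------------------------------------------
# Innervation CSV
# ---------------------------------------------------------------------------

@dataclass
class InnervationTable:
    """Neurite path length (micrometres) of each neuron in each region."""

    table: pd.DataFrame  # columns: neuron_id, cell_type, one per region

    def __post_init__(self):
        required = {"neuron_id", "cell_type"}
        if not required <= set(self.table.columns):
            raise FormatError("innervation table needs neuron_id and "
                              "cell_type columns")

    @property
    def regions(self) -> List[str]:
        return [c for c in self.table.columns
                if c not in ("neuron_id", "cell_type")]

    def row(self, neuron_id) -> pd.Series:
        sel = self.table[self.table["neuron_id"] == neuron_id]
        if sel.empty:
            raise KeyError(f"neuron {neuron_id} not in table")
        return sel.iloc[0]


def _validate_cell_types(table: pd.DataFrame) -> pd.DataFrame:
    bad = ~table["cell_type"].isin(CELL_TYPES)
    if bad.any():
        unknown = sorted(table.loc[bad, "cell_type"].unique())
        warnings.warn(f"unknown cell type label(s) {unknown} mapped to 'other'",
                      stacklevel=3)
        table.loc[bad, "cell_type"] = "other"
    return table


def write_innervation_csv(table: InnervationTable,
                          path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# neurite length per region in micrometers (um)\n")
        table.table.to_csv(fh, index=False)


def read_innervation_csv(path: Union[str, Path]) -> InnervationTable:
    df = pd.read_csv(path, comment="#")
    if df.empty and "neuron_id" not in df.columns:
        raise FormatError(f"{path}: missing header row")
    df = _validate_cell_types(df)
    for col in df.columns:
        if col in ("neuron_id", "cell_type"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            raise FormatError(f"non-numeric length in column {col!r}")
        df[col] = vals
    return InnervationTable(df)
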