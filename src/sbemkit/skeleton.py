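"""Node-and-edge skeleton representation of a traced neuron.

A skeleton is a graph of 3-D nodes connected by undirected edges; for a
manually traced neurite it is a tree, but the container does not enforce
acyclicity (consolidation intermediates may briefly hold forests).
Positions are plain float triplets; whether they denote voxel indices or
nanometres is decided by the caller, with :meth:`Skeleton.scaled` converting
between the two using the anisotropic voxel pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Set, Tuple

import numpy as np

__all__ = ["SkeletonNode", "Skeleton", "DEFAULT_SCALE"]

#: Voxel pitch of the reference SBEM stack in nm (x, y, z).
DEFAULT_SCALE = (9.25, 9.25, 25.0)


@dataclass
class SkeletonNode:
    node_id: int
    position: np.ndarray  # (3,) float
    radius: float = 1.0
    time: Optional[float] = None
    comment: Optional[str] = None
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.node_id}: position must be a finite 3-vector")


class Skeleton:
    """A set of nodes plus undirected edges between them."""

    def __init__(self, thing_id: int = 1, name: str = "",
                 nodes: Optional[Iterable[SkeletonNode]] = None,
                 edges: Optional[Iterable[Tuple[int, int]]] = None,
                 meta: Optional[dict] = None) -> None:
        self.thing_id = int(thing_id)
        self.name = name
        self.nodes: Dict[int, SkeletonNode] = {}
        self.edges: Set[Tuple[int, int]] = set()
        self.meta: dict = dict(meta or {})
        for n in nodes or ():
            self.add_node(n)
        for a, b in edges or ():
            self.add_edge(a, b)

    # -- construction -------------------------------------------------
    def add_node(self, node: SkeletonNode) -> SkeletonNode:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id}")
        self.nodes[node.node_id] = node
        return node

    def new_node(self, position, **kw) -> SkeletonNode:
        nid = max(self.nodes, default=0) + 1
        return self.add_node(SkeletonNode(nid, np.asarray(position, float), **kw))

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError(f"self-edge at node {a}")
        for nid in (a, b):
            if nid not in self.nodes:
                raise KeyError(f"edge ({a}, {b}) references missing node {nid}")
        self.edges.add((a, b) if a < b else (b, a))

    def remove_node(self, node_id: int) -> None:
        del self.nodes[node_id]
        self.edges = {e for e in self.edges if node_id not in e}

    # -- queries ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def neighbors(self, node_id: int) -> Iterator[int]:
        for a, b in self.edges:
            if a == node_id:
                yield b
            elif b == node_id:
                yield a

    def adjacency(self) -> Dict[int, list]:
        adj: Dict[int, list] = {nid: [] for nid in self.nodes}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def degree(self, node_id: int) -> int:
        return sum(1 for _ in self.neighbors(node_id))

    def edge_length(self, edge: Tuple[int, int]) -> float:
        a, b = edge
        return float(np.linalg.norm(self.nodes[a].position - self.nodes[b].position))

    def total_length(self) -> float:
        """Summed edge length, in the units of the node positions."""
        return float(sum(self.edge_length(e) for e in self.edges))

    def components(self) -> list:
        """Connected components as lists of node ids (BFS, deterministic)."""
        adj = self.adjacency()
        seen: Set[int] = set()
        comps = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            comp = []
            stack = [start]
            seen.add(start)
            while stack:
                nid = stack.pop()
                comp.append(nid)
                for m in adj[nid]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            comps.append(sorted(comp))
        return comps

    def is_tree(self) -> bool:
        return (len(self.components()) == 1
                and len(self.edges) == len(self.nodes) - 1)

    # -- transforms ---------------------------------------------------
    def copy(self) -> "Skeleton":
        out = Skeleton(self.thing_id, self.name, meta=dict(self.meta))
        for nid, n in self.nodes.items():
            out.nodes[nid] = SkeletonNode(nid, n.position.copy(), n.radius,
                                          n.time, n.comment, dict(n.extra))
        out.edges = set(self.edges)
        return out

    def scaled(self, scale=DEFAULT_SCALE) -> "Skeleton":
        """Return a copy with positions multiplied per-axis by ``scale``.

        Typical use: convert voxel-index positions to nm with the
        anisotropic pitch (9.25, 9.25, 25) nm.
        """
        s = np.asarray(scale, float)
        out = self.copy()
        for n in out.nodes.values():
            n.position = n.position * s
        return out

    def positions(self, order: Optional[list] = None) -> np.ndarray:
        ids = order if order is not None else sorted(self.nodes)
        return np.array([self.nodes[i].position for i in ids], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Skeleton(id={self.thing_id}, name={self.name!r}, "
                f"{len(self.nodes)} nodes, {len(self.edges)} edges)")
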