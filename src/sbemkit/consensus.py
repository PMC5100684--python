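"""Redundancy-based skeleton consolidation with expert arbitration.

Several independent tracings of the same neuron are combined into one
consensus skeleton: tracings are resampled to ~100 nm node spacing, nodes
from different tracings are grouped into *cliques* by spatial proximity
and connectedness (region growing along the skeletons, so parallel
neurites cannot be conflated), the cliques' centroids become the
consolidated skeleton, and every point where one tracing diverges from the
agreement — an extra branch, a branch missed by the majority, or an early
termination — is flagged as a *mismatch point*. Mismatches are resolved by
local re-tracings (majority vote) or by a direct expert decision, and the
whole cycle repeats until no open mismatch remains.

All geometry is in nanometres; convert voxel-index skeletons with
:meth:`sbemkit.skeleton.Skeleton.scaled` first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import NonConvergenceError, ParameterError
from .skeleton import Skeleton, SkeletonNode

__all__ = [
    "ResampledSkeleton", "Clique", "MismatchPoint", "ConsolidatedSkeleton",
    "resample", "form_cliques", "consolidate", "find_mismatches",
    "resolve", "core_iterate", "make_oracle_resolver", "clip_to_ball",
]

DEFAULT_SPACING = 100.0   # nm, target inter-node spacing after resampling
DEFAULT_RADIUS = 500.0    # nm, clique radius; >> node spacing, << inter-neurite


class ResampledSkeleton:
    """A tracing resampled to a maximum inter-node spacing.

    Nodes are indexed 0..n-1; ``provenance[i]`` is the original node id for
    retained original nodes and ``None`` for nodes inserted along an edge.
    All original nodes (hence every branch point and endpoint) are retained
    and inserted nodes lie on the original polyline, so the total path
    length is preserved exactly.
    """

    def __init__(self, source_tracing: int, positions: np.ndarray,
                 edges: List[Tuple[int, int]],
                 provenance: List[Optional[int]]):
        self.source_tracing = source_tracing
        self.positions = np.asarray(positions, float)
        self.edges = edges
        self.provenance = provenance
        self.adj: List[List[int]] = [[] for _ in range(len(self.positions))]
        for a, b in edges:
            self.adj[a].append(b)
            self.adj[b].append(a)

    def __len__(self) -> int:
        return len(self.positions)

    def total_length(self) -> float:
        return float(sum(np.linalg.norm(self.positions[a] - self.positions[b])
                         for a, b in self.edges))

    def degree(self, i: int) -> int:
        return len(self.adj[i])


def resample(skeleton: Skeleton, target_spacing: float = DEFAULT_SPACING,
             source_tracing: int = 0) -> ResampledSkeleton:
    """Resample a tracing so no edge exceeds ``target_spacing``.

    Each edge of length L is subdivided into ``ceil(L / target_spacing)``
    uniform pieces; original nodes are kept, so arc length is unchanged.
    """
    if target_spacing <= 0:
        raise ParameterError("target_spacing must be positive")
    ids = sorted(skeleton.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    positions = [skeleton.nodes[nid].position.astype(float) for nid in ids]
    provenance: List[Optional[int]] = list(ids)
    edges: List[Tuple[int, int]] = []
    for a, b in sorted(skeleton.edges):
        pa, pb = skeleton.nodes[a].position, skeleton.nodes[b].position
        length = float(np.linalg.norm(pb - pa))
        nseg = max(1, math.ceil(length / target_spacing - 1e-12))
        prev = index[a]
        for k in range(1, nseg):
            positions.append(pa + (pb - pa) * (k / nseg))
            provenance.append(None)
            cur = len(positions) - 1
            edges.append((prev, cur))
            prev = cur
        edges.append((prev, index[b]))
    return ResampledSkeleton(source_tracing, np.array(positions), edges,
                             provenance)


@dataclass
class Clique:
    """Agreement unit: at most one node per tracing, all mutually within
    the clique radius; the consensus position is the member centroid."""

    members: Dict[int, int]            # tracing id -> resampled node index
    consensus_position: np.ndarray

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MismatchPoint:
    position: np.ndarray
    kind: str                          # extra-branch | missing-branch | early-termination
    involved: List[int]                # tracing ids
    orphan_nodes: List[Tuple[int, int]] = field(default_factory=list)
    resolved: bool = False
    resolution: Optional[tuple] = None


@dataclass
class ConsolidatedSkeleton:
    skeleton: Skeleton                 # one node per clique, consensus nm
    cliques: List[Clique]
    open_mismatches: List[MismatchPoint] = field(default_factory=list)
    audit: List[dict] = field(default_factory=list)


def _pairwise_ok(points: List[np.ndarray], radius: float) -> bool:
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.linalg.norm(points[i] - points[j]) > radius:
                return False
    return True


def form_cliques(tracings: Sequence[ResampledSkeleton], radius: float = DEFAULT_RADIUS,
                 min_agreement: int = 2,
                 max_spread_factor: Optional[float] = None
                 ) -> Tuple[List[Clique], List[Tuple[int, int]]]:
    """Group nodes of redundant tracings into cliques by region growing.

    Growth starts from a seed tuple of mutually nearby nodes (one per
    tracing, scanned from the lowest node ids, i.e. near the tracing
    start) and proceeds along skeleton connectivity: a node can only join
    a clique if it is a polyline neighbor of an already-assigned node.
    Among the current frontier, the candidate clique with the smallest
    summed pairwise member distance is formed first (ties broken by
    tracing/node id), which keeps true correspondences ahead of spurious
    ones. When growth stalls, seeding is retried among the remaining
    unassigned nodes, so agreement resumes past local disagreements.

    Returns the cliques (each with ``len >= min_agreement``) and the
    orphan nodes ``(tracing_id, node_index)`` that joined none.
    """
    if len(tracings) < 2:
        raise ParameterError("need at least two tracings")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if min_agreement > len(tracings):
        raise ParameterError(
            f"min_agreement {min_agreement} exceeds {len(tracings)} tracings")
    tids = [tr.source_tracing for tr in tracings]
    if len(set(tids)) != len(tids):
        raise ParameterError("tracing ids must be unique")
    # order by stable tracing id so output is input-order independent
    trs = {tr.source_tracing: tr for tr in tracings}
    order = sorted(trs)
    assigned: Dict[int, np.ndarray] = {
        t: np.full(len(trs[t]), -1, dtype=int) for t in order}

    def unassigned(t):
        return np.nonzero(assigned[t] == -1)[0]

    clique_adj: List[Set[int]] = []

    def neighbor_cliques(t: int, n: int) -> Set[int]:
        return {int(assigned[t][m]) for m in trs[t].adj[n]
                if assigned[t][m] != -1}

    def compatible(cset: Set[int], max_hops: int = 3) -> bool:
        """All cliques in ``cset`` within a few hops of each other in the
        clique-adjacency graph built so far. Prevents nodes from distant
        path sections (parallel or looping neurites passing within the
        clique radius) from being conflated into one clique."""
        if len(cset) <= 1:
            return True
        start = min(cset)
        seen = {start}
        frontier = {start}
        for _ in range(max_hops):
            frontier = {m for c in frontier for m in clique_adj[c]} - seen
            seen |= frontier
            if cset <= seen:
                return True
        return cset <= seen

    def build_candidate(pivot_t: int, pivot_n: int,
                        pool: Dict[int, List[int]]) -> Tuple[Dict[int, int], float]:
        members = {pivot_t: pivot_n}
        pts = [trs[pivot_t].positions[pivot_n]]
        cset = set(neighbor_cliques(pivot_t, pivot_n))
        for t in order:
            if t == pivot_t or t not in pool:
                continue
            opts = []
            for n in pool[t]:
                d = float(np.linalg.norm(trs[t].positions[n]
                                         - trs[pivot_t].positions[pivot_n]))
                if d <= radius:
                    opts.append((d, n))
            for d, n in sorted(opts):
                p = trs[t].positions[n]
                ncs = neighbor_cliques(t, n)
                if _pairwise_ok(pts + [p], radius) and compatible(cset | ncs):
                    members[t] = n
                    pts.append(p)
                    cset |= ncs
                    break
        score = 0.0
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                score += float(np.linalg.norm(pts[i] - pts[j]))
        return members, score

    def best_from_pool(pool: Dict[int, List[int]]) -> Optional[Dict[int, int]]:
        # maximal agreement first, then smallest mean pairwise distance
        best = None
        best_key = None
        for t in sorted(pool):
            for n in pool[t]:
                members, score = build_candidate(t, n, pool)
                if len(members) < min_agreement:
                    continue
                npairs = len(members) * (len(members) - 1) / 2
                key = (-len(members), score / npairs, t, int(n))
                if best_key is None or key < best_key:
                    best, best_key = members, key
        return best

    def frontier_pool() -> Dict[int, List[int]]:
        pool: Dict[int, List[int]] = {}
        for t in order:
            tr = trs[t]
            asg = assigned[t]
            sel = [int(n) for n in unassigned(t)
                   if any(asg[m] != -1 for m in tr.adj[n])]
            if sel:
                pool[t] = sel
        return pool

    def seed_pool(fresh_only: bool) -> Dict[int, List[int]]:
        pool: Dict[int, List[int]] = {}
        for t in order:
            sel = [int(n) for n in unassigned(t)
                   if not (fresh_only and neighbor_cliques(t, n))]
            if sel:
                pool[t] = sel
        return pool

    def best_seed() -> Optional[Dict[int, int]]:
        """Seed growth anew among nodes not yet adjacent to any clique.

        Only *fresh* nodes (no assigned polyline neighbor) may seed, and
        the tuple's mean pairwise distance must be well below the clique
        radius: nodes left over next to existing cliques are resampling
        slack, and allowing them to seed would let path sections that merely
        loop close to each other be conflated.
        """
        fresh = not cliques
        pool = seed_pool(fresh_only=not fresh)
        best, best_key = None, None
        for t in sorted(pool):
            for n in pool[t]:
                members, score = build_candidate(t, n, pool)
                if len(members) < min_agreement:
                    continue
                npairs = len(members) * (len(members) - 1) / 2
                if not fresh and score / npairs > radius / 2:
                    continue
                key = (-len(members), score / npairs, t, int(n))
                if best_key is None or key < best_key:
                    best, best_key = members, key
        return best

    cliques: List[Clique] = []
    while True:
        members = best_from_pool(frontier_pool())
        if members is None:
            members = best_seed()
            if members is None:
                break
        pts = np.array([trs[t].positions[n] for t, n in sorted(members.items())])
        clique = Clique(members=dict(sorted(members.items())),
                        consensus_position=pts.mean(axis=0))
        ci = len(cliques)
        cliques.append(clique)
        clique_adj.append(set())
        for t, n in members.items():
            assigned[t][n] = ci
            for cj in neighbor_cliques(t, n):
                if cj != ci:
                    clique_adj[ci].add(cj)
                    clique_adj[cj].add(ci)

    # demote outlier cliques: member spreads far above the run's typical
    # agreement indicate cross-matched strands (e.g. near branch points),
    # not consensus
    if cliques and max_spread_factor is not None:
        def spread(c):
            pts = [trs[t].positions[n] for t, n in c.members.items()]
            npairs = len(pts) * (len(pts) - 1) / 2
            return sum(float(np.linalg.norm(pts[i] - pts[j]))
                       for i in range(len(pts))
                       for j in range(i + 1, len(pts))) / npairs
        spreads = np.array([spread(c) for c in cliques])
        cut = max(4 * float(np.median(spreads)), 1e-9)
        kept = [c for c, s in zip(cliques, spreads) if s <= cut]
        for c, s in zip(cliques, spreads):
            if s > cut:
                for t, n in c.members.items():
                    assigned[t][n] = -1
        cliques = kept

    orphans = [(t, int(n)) for t in order for n in unassigned(t)]
    return cliques, orphans


def _assignment_maps(tracings, cliques):
    trs = {tr.source_tracing: tr for tr in tracings}
    assigned = {t: np.full(len(trs[t]), -1, dtype=int) for t in trs}
    for ci, cl in enumerate(cliques):
        for t, n in cl.members.items():
            assigned[t][n] = ci
    return trs, assigned


def consolidate(cliques: Sequence[Clique],
                tracings: Sequence[ResampledSkeleton]) -> ConsolidatedSkeleton:
    """Build the consensus skeleton: one node per clique at its centroid,
    an edge between two cliques wherever some tracing connects them
    (directly, or through a run of its own unassigned nodes)."""
    trs, assigned = _assignment_maps(tracings, cliques)
    skel = Skeleton(name="consolidated")
    for ci, cl in enumerate(cliques):
        skel.add_node(SkeletonNode(ci + 1, cl.consensus_position))
    edges: Set[Tuple[int, int]] = set()
    for t in sorted(trs):
        tr = trs[t]
        asg = assigned[t]
        for a, b in tr.edges:
            if asg[a] != -1 and asg[b] != -1 and asg[a] != asg[b]:
                edges.add((min(asg[a], asg[b]), max(asg[a], asg[b])))
        # contract short runs of unassigned nodes between two assigned
        # nodes (resampling slack); long runs are real disagreements and
        # must not be bridged with a chord
        seen: Set[int] = set()
        for start in range(len(tr)):
            if asg[start] != -1 or start in seen:
                continue
            comp = [start]
            seen.add(start)
            stack = [start]
            touching: Set[int] = set()
            while stack:
                n = stack.pop()
                for m in tr.adj[n]:
                    if asg[m] != -1:
                        touching.add(int(asg[m]))
                    elif m not in seen:
                        seen.add(m)
                        stack.append(m)
                        comp.append(m)
            if len(comp) > 2:
                continue
            for ca in touching:
                for cb in touching:
                    if ca < cb:
                        edges.add((ca, cb))
    # prune triangle chords: tracings resampled to slightly different node
    # counts can skip a clique, adding a redundant long edge across two
    # consecutive ones; drop the longest edge of any such triangle
    adj: Dict[int, Set[int]] = {}
    for ca, cb in edges:
        adj.setdefault(ca, set()).add(cb)
        adj.setdefault(cb, set()).add(ca)

    def elen(e):
        return float(np.linalg.norm(cliques[e[0]].consensus_position
                                    - cliques[e[1]].consensus_position))

    for e in sorted(edges, key=lambda e: (-elen(e), e)):
        ca, cb = e
        common = adj.get(ca, set()) & adj.get(cb, set())
        if any(elen((ca, c)) <= elen(e) and elen((c, cb)) <= elen(e)
               for c in common):
            edges.discard(e)
            adj[ca].discard(cb)
            adj[cb].discard(ca)
    for ca, cb in edges:
        skel.add_edge(ca + 1, cb + 1)
    return ConsolidatedSkeleton(skeleton=skel, cliques=list(cliques))


def find_mismatches(tracings: Sequence[ResampledSkeleton],
                    cliques: Sequence[Clique],
                    orphans: Sequence[Tuple[int, int]],
                    radius: float = DEFAULT_RADIUS,
                    min_agreement: int = 2) -> List[MismatchPoint]:
    """Locate the divergence points between tracings.

    One mismatch per connected orphan component, positioned at the orphan
    node adjacent to an assigned node; components that never leave the
    clique radius of the consensus are resampling slack, not divergences,
    and are skipped. Additionally, an early-termination mismatch is
    reported wherever one tracing ends while the consensus (supported by
    ``min_agreement`` other tracings) continues past its endpoint by more
    than ``2 * radius`` of path length.
    """
    trs, assigned = _assignment_maps(tracings, cliques)
    out: List[MismatchPoint] = []
    consensus = (np.array([c.consensus_position for c in cliques])
                 if cliques else np.zeros((0, 3)))
    ctree = cKDTree(consensus) if len(consensus) else None

    orphan_set = set(orphans)
    visited: Set[Tuple[int, int]] = set()
    for t, n in sorted(orphans):
        if (t, n) in visited:
            continue
        comp = [(t, n)]
        visited.add((t, n))
        stack = [n]
        while stack:
            cur = stack.pop()
            for m in trs[t].adj[cur]:
                if (t, m) in orphan_set and (t, m) not in visited:
                    visited.add((t, m))
                    stack.append(m)
                    comp.append((t, m))
        pts = np.array([trs[tt].positions[nn] for tt, nn in comp])
        if ctree is not None:
            dists, _ = ctree.query(pts)
            if np.all(dists <= radius):
                continue  # within agreement slack everywhere
        # divergence point: orphan node adjacent to an assigned node
        div = None
        for tt, nn in sorted(comp):
            if any(assigned[tt][m] != -1 for m in trs[tt].adj[nn]):
                div = (tt, nn)
                break
        if div is None:
            div = sorted(comp)[0]
        # another tracing supports this segment only if its own orphans
        # cover most of the component, not merely its divergence point
        home = comp[0][0]
        support = {home}
        for ot in trs:
            if ot == home:
                continue
            others = np.array([trs[ot].positions[nn]
                               for tt2, nn in orphans if tt2 == ot])
            if len(others) == 0:
                continue
            otree = cKDTree(others)
            dists, _ = otree.query(pts)
            if np.mean(dists <= radius) >= 0.5:
                support.add(ot)
        kind = "missing-branch" if len(support) >= min_agreement else "extra-branch"
        out.append(MismatchPoint(
            position=trs[div[0]].positions[div[1]].copy(), kind=kind,
            involved=[home] + sorted(support - {home}),
            orphan_nodes=sorted(comp)))

    # early terminations: a tracing's endpoint where the consensus goes on
    # without any coverage by that tracing
    if cliques:
        cons = consolidate(cliques, tracings)
        cadj = cons.skeleton.adjacency()
        ttrees = {t: cKDTree(trs[t].positions) for t in trs}
        for t in sorted(trs):
            tr = trs[t]
            asg = assigned[t]
            for n in range(len(tr)):
                if tr.degree(n) > 1 or asg[n] == -1:
                    continue
                c0 = int(asg[n])
                # BFS into consensus regions genuinely uncovered by tracing
                # t: no member from t and no node of t (clique or orphan)
                # within the clique radius
                best = 0.0
                dist = {c0: 0.0}
                stack = [c0]
                while stack:
                    c = stack.pop()
                    for m1 in cadj[c + 1]:
                        c2 = m1 - 1
                        if c2 in dist or t in cliques[c2].members:
                            continue
                        if len(cliques[c2]) < min_agreement:
                            continue
                        # only uncovered stretches count toward the missing
                        # length; covered cliques are traversed for free
                        covered = (ttrees[t].query(
                            cliques[c2].consensus_position)[0] <= radius)
                        step = 0.0 if covered else float(
                            np.linalg.norm(cliques[c2].consensus_position
                                           - cliques[c].consensus_position))
                        dist[c2] = dist[c] + step
                        best = max(best, dist[c2])
                        stack.append(c2)
                if best > 2 * radius:
                    out.append(MismatchPoint(
                        position=cliques[c0].consensus_position.copy(),
                        kind="early-termination", involved=[t]))
    return out


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------

def clip_to_ball(skeleton: Skeleton, center: Sequence[float],
                 radius: float, local_component: bool = True) -> Skeleton:
    """Sub-skeleton of nodes within ``radius`` of ``center`` (nm).

    With ``local_component`` (default) only the connected piece closest to
    the center is returned — the local segment a tracer asked to re-trace
    around a point would produce — rather than every unrelated branch that
    happens to cross the ball.
    """
    center = np.asarray(center, float)
    out = Skeleton(thing_id=skeleton.thing_id, name=f"{skeleton.name}_local")
    keep = {nid for nid, node in skeleton.nodes.items()
            if np.linalg.norm(node.position - center) <= radius}
    for nid in sorted(keep):
        n = skeleton.nodes[nid]
        out.add_node(SkeletonNode(nid, n.position.copy(), n.radius))
    for a, b in skeleton.edges:
        if a in keep and b in keep:
            out.add_edge(a, b)
    if local_component and len(out.nodes):
        comps = out.components()
        def comp_dist(comp):
            pts = np.array([out.nodes[i].position for i in comp])
            return float(np.min(np.linalg.norm(pts - center, axis=1)))
        nearest = min(comps, key=lambda c: (comp_dist(c), c[0]))
        for comp in comps:
            if comp is not nearest:
                for nid in comp:
                    out.remove_node(nid)
    return out


def _drop_segment(tracing: Skeleton, mismatch: MismatchPoint,
                  tracings_res: Dict[int, ResampledSkeleton],
                  radius: float = DEFAULT_RADIUS) -> None:
    """Delete the contested segment from the minority tracing.

    The orphan component's original nodes are removed, then the stub it
    hung from is peeled back: the first stretch of a spurious branch can
    run within the clique radius of the true path (and thus join cliques
    instead of the orphan set), so exposed chain ends near the removed
    segment are deleted until a branch point or distant structure is
    reached.
    """
    tid = mismatch.involved[0] if mismatch.involved else None
    removed = 0
    exposed: List[int] = []
    for t, n in mismatch.orphan_nodes:
        if t != tid:
            continue
        orig = tracings_res[t].provenance[n]
        if orig is not None and orig in tracing.nodes and tracing.degree(orig) <= 2:
            exposed.extend(m for m in tracing.neighbors(orig))
            tracing.remove_node(orig)
            removed += 1
    if removed:
        # peel the exposed stub back while no other tracing corroborates
        # it: the first stretch of a spurious branch can run inside the
        # clique radius of the true path and sneak into cliques there
        others = np.concatenate([tracings_res[t].positions
                                 for t in tracings_res if t != tid])
        otree = cKDTree(others)
        corroboration = radius / 4
        stack = [nid for nid in exposed if nid in tracing.nodes]
        while stack:
            nid = stack.pop()
            if nid not in tracing.nodes or tracing.degree(nid) > 1:
                continue
            if otree.query(tracing.nodes[nid].position)[0] <= corroboration:
                continue
            nbrs = list(tracing.neighbors(nid))
            tracing.remove_node(nid)
            stack.extend(nbrs)
    # drop any nodes disconnected from the main component
    comps = tracing.components()
    if len(comps) > 1:
        main = max(comps, key=len)
        for comp in comps:
            if comp is not main:
                for nid in comp:
                    tracing.remove_node(nid)


def _splice(tracing: Skeleton, retracing: Skeleton, spacing: float) -> int:
    """Merge a local retracing into a tracing.

    Only the genuinely new part of the retracing is taken: nodes within
    1.5 node spacings of existing structure are considered already covered
    and are dropped (adding them would braid a near-duplicate strand along
    the existing path). The remaining nodes are added with fresh ids,
    retracing edges among them are kept, and each added fragment of
    at least 3 nodes is connected to the nearest existing tracing node.
    Returns the number of nodes added.
    """
    existing_ids = sorted(tracing.nodes)
    existing = np.array([tracing.nodes[i].position for i in existing_ids])
    tree = cKDTree(existing)
    id_map: Dict[int, int] = {}
    for rid in sorted(retracing.nodes):
        pos = retracing.nodes[rid].position
        d, _ = tree.query(pos)
        if d > 1.5 * spacing:
            id_map[rid] = tracing.new_node(pos.copy()).node_id
    added = set(id_map.values())
    for a, b in retracing.edges:
        if a in id_map and b in id_map:
            tracing.add_edge(id_map[a], id_map[b])
    for comp in tracing.components():
        if set(comp) <= added:
            if len(comp) < 3:   # shards from jitter outliers, not structure
                for nid in comp:
                    tracing.remove_node(nid)
                continue
            pts = np.array([tracing.nodes[i].position for i in comp])
            d, j = tree.query(pts)
            k = int(np.argmin(d))
            tracing.add_edge(comp[k], existing_ids[int(j[k])])
    return len(added)


def resolve(mismatch: MismatchPoint, tracings: Dict[int, Skeleton],
            local_retracings: Sequence[Skeleton], policy,
            tracings_res: Optional[Dict[int, ResampledSkeleton]] = None,
            radius: float = DEFAULT_RADIUS,
            spacing: float = DEFAULT_SPACING) -> None:
    """Apply one resolution to the tracings, in place.

    ``policy`` is ``("expert", "drop"|"keep")`` or ``"majority"``. Expert
    ``drop`` deletes the contested segment from the minority tracing;
    ``keep`` accepts it as is. Majority takes the vote of the local
    retracings: for an early termination, the retracing is spliced into
    the tracing that stopped; for a contested branch, the branch is kept
    if at least half the retracings cover it and dropped otherwise.
    Resolving an already-resolved mismatch is a no-op.
    """
    if mismatch.resolved:
        return
    if policy == "majority" or (isinstance(policy, tuple) and policy[0] == "majority"):
        if not local_retracings:
            raise ParameterError("majority resolution requires retracings")
        ball = 10 * radius
        for rt in local_retracings:
            pts = rt.positions()
            if len(pts) == 0 or np.min(np.linalg.norm(
                    pts - mismatch.position, axis=1)) > ball:
                raise ParameterError(
                    "retracing does not overlap the mismatch ball")
        if mismatch.kind == "early-termination":
            tid = mismatch.involved[0]
            _splice(tracings[tid], local_retracings[0], spacing)
            mismatch.resolution = ("majority", "spliced")
        else:
            votes = 0
            seg = np.array([tracings_res[t].positions[n]
                            for t, n in mismatch.orphan_nodes]) \
                if tracings_res and mismatch.orphan_nodes \
                else mismatch.position[None, :]
            for rt in local_retracings:
                pts = rt.positions()
                tree = cKDTree(pts)
                d, _ = tree.query(seg)
                if np.mean(d <= radius) >= 0.5:
                    votes += 1
            if votes * 2 >= len(local_retracings):
                mismatch.resolution = ("majority", "kept")
            else:
                tid = mismatch.involved[0]
                _drop_segment(tracings[tid], mismatch, tracings_res, radius)
                mismatch.resolution = ("majority", "dropped")
    elif isinstance(policy, tuple) and policy[0] == "expert":
        decision = policy[1]
        if decision == "drop":
            if mismatch.kind == "early-termination":
                mismatch.resolution = ("expert", "kept-short")
            else:
                tid = mismatch.involved[0]
                _drop_segment(tracings[tid], mismatch, tracings_res, radius)
                mismatch.resolution = ("expert", "dropped")
        elif decision == "keep":
            mismatch.resolution = ("expert", "kept")
        else:
            raise ParameterError(f"unknown expert decision {decision!r}")
    else:
        raise ParameterError(f"unknown policy {policy!r}")
    mismatch.resolved = True


def make_oracle_resolver(ground_truth: Skeleton, ball: float = 10000.0,
                         tolerance: float = 250.0) -> Callable:
    """A simulated expert + tracer pool backed by a known true skeleton.

    Contested segments are kept or dropped depending on whether the truth
    covers them (within ``tolerance``); early terminations are answered
    with two clean local re-tracings clipped from the truth around the
    mismatch point (radius ``ball`` nm).
    """
    pts = ground_truth.positions()
    tree = cKDTree(pts)

    def resolver(mismatch: MismatchPoint,
                 tracings_res: Optional[Dict[int, ResampledSkeleton]] = None):
        if mismatch.kind == "early-termination":
            seg = clip_to_ball(ground_truth, mismatch.position, ball)
            return ("majority", [seg, seg])
        if tracings_res and mismatch.orphan_nodes:
            seg = np.array([tracings_res[t].positions[n]
                            for t, n in mismatch.orphan_nodes])
        else:
            seg = mismatch.position[None, :]
        d, _ = tree.query(seg)
        covered = np.mean(d <= tolerance) >= 0.5
        return ("expert", "keep" if covered else "drop")

    return resolver


def core_iterate(tracings: Sequence[Skeleton], radius: float = DEFAULT_RADIUS,
                 min_agreement: int = 2, resolver: Optional[Callable] = None,
                 target_spacing: float = DEFAULT_SPACING,
                 max_rounds: int = 50) -> ConsolidatedSkeleton:
    """Iterate clique formation, consolidation and mismatch resolution.

    Each round resamples the (possibly corrected) tracings, forms cliques,
    builds the consensus and detects mismatches; every open mismatch is
    passed to ``resolver(mismatch, resampled_by_id)`` which must return a
    policy for :func:`resolve`. Mismatches resolved by keeping the status
    quo are remembered and not re-raised. Terminates when a round produces
    no open mismatch; raises :class:`NonConvergenceError` after
    ``max_rounds``.
    """
    work = {i: s.copy() for i, s in enumerate(tracings)}
    suppressed: List[Tuple[str, np.ndarray]] = []
    audit: List[dict] = []
    last = None
    for rnd in range(1, max_rounds + 1):
        res = {t: resample(work[t], target_spacing, source_tracing=t)
               for t in sorted(work)}
        cliques, orphans = form_cliques(list(res.values()), radius,
                                        min_agreement)
        cons = consolidate(cliques, list(res.values()))
        mismatches = find_mismatches(list(res.values()), cliques, orphans,
                                     radius, min_agreement)
        mismatches = [m for m in mismatches
                      if not any(m.kind == k
                                 and np.linalg.norm(m.position - p) <= 2 * radius
                                 for k, p in suppressed)]
        audit.append({"round": rnd, "n_cliques": len(cliques),
                      "n_orphans": len(orphans),
                      "mismatches": [(m.kind, m.position.tolist())
                                     for m in mismatches]})
        cons.audit = audit
        last = cons
        if not mismatches:
            cons.open_mismatches = []
            return cons
        if resolver is None:
            cons.open_mismatches = mismatches
            raise NonConvergenceError(mismatches, rnd)
        for m in mismatches:
            policy = resolver(m, res)
            retracings: Sequence[Skeleton] = ()
            if isinstance(policy, tuple) and policy[0] == "majority":
                retracings = policy[1]
                policy = "majority"
            resolve(m, work, retracings, policy, tracings_res=res,
                    radius=radius, spacing=target_spacing)
            if m.resolution and m.resolution[1] in ("kept", "kept-short"):
                suppressed.append((m.kind, m.position.copy()))
    last.open_mismatches = mismatches
    raise NonConvergenceError(mismatches, max_rounds)
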