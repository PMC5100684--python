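"""Seeded generators for synthetic test inputs.

Everything downstream — tile registration, the cube store, skeleton
consensus, morphometry — can be exercised without any microscope data:
this module fabricates textured block-face-like tiles with known offsets,
tile grids with realistic 5-8% overlap, random branching skeletons, tracer
error perturbations (positional jitter, truncated terminal subtrees,
spurious grafted branches) and convex glomerulus-like point clouds.

All generators are pure functions of their arguments: the same seed yields
bit-identical output, and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .skeleton import Skeleton, SkeletonNode

__all__ = [
    "TextureSpec", "GroundTruthGrid", "PerturbationSpec",
    "gen_texture", "gen_tile_pair", "gen_tile_grid",
    "gen_skeleton", "perturb_skeleton", "gen_convex_region",
]

U16_MAX = 65535


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of a band-limited random texture.

    ``correlation_length`` (pixels) sets the spatial scale of the blobs:
    white noise is low-pass filtered with a Gaussian kernel of this width,
    which guarantees a single sharp autocorrelation peak, much like
    membrane-rich EM texture. ``noise_sd`` adds white noise as a fraction
    of the full intensity range after filtering.
    """

    width: int
    height: int
    correlation_length: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 16 or self.height < 16:
            raise ParameterError("texture dimensions must be >= 16 pixels")
        if self.correlation_length < 1:
            raise ParameterError("correlation_length must be >= 1 pixel")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass
class GroundTruthGrid:
    """A tile grid with exactly known mosaic positions."""

    tiles: List[np.ndarray]
    true_positions: List[Tuple[int, int]]  # (x, y) per tile, mosaic pixels
    grid_shape: Tuple[int, int]            # (rows, cols)
    tile_size: int
    overlap_fraction: float
    texture: np.ndarray = field(repr=False, default=None)

    def grid_index(self, tile_id: int) -> Tuple[int, int]:
        rows, cols = self.grid_shape
        return divmod(tile_id, cols)


@dataclass(frozen=True)
class PerturbationSpec:
    """Tracer-error model: jitter + the two error classes seen in manual
    tracing, missed processes (truncation of a terminal subtree) and
    wrongly traced processes (grafted spurious branches)."""

    jitter_sd: float = 0.0          # nm
    truncate_fraction: float = 0.0  # of total path length
    graft_length: float = 0.0       # nm per grafted branch
    graft_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if min(self.jitter_sd, self.truncate_fraction,
               self.graft_length, self.graft_count) < 0:
            raise ParameterError("perturbation magnitudes must be non-negative")
        if self.truncate_fraction >= 1:
            raise ParameterError("truncate_fraction must be < 1")


def gen_texture(spec: TextureSpec) -> np.ndarray:
    """Generate a 16-bit band-limited random texture.

    Returns a ``(height, width)`` uint16 raster whose autocorrelation has a
    strictly dominant zero-lag peak, so translational registration against
    it is well posed.
    """
    rng = np.random.default_rng(spec.seed)
    img = rng.standard_normal((spec.height, spec.width))
    img = ndimage.gaussian_filter(img, spec.correlation_length, mode="reflect")
    img = (img - img.min()) / (img.max() - img.min() + 1e-30)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img * U16_MAX), 0, U16_MAX).astype(np.uint16)


def gen_tile_pair(texture: np.ndarray, offset: Tuple[int, int],
                  tile_size: int, noise_sd: float = 0.0,
                  seed: int = 0) -> Tuple[np.ndarray, np.ndarray, Tuple[int, int]]:
    """Cut two overlapping tiles out of one texture.

    Tile B sits at mosaic position ``offset = (dx, dy)`` relative to tile A:
    before noise, ``B[y, x] == A[y + dy, x + dx]`` wherever both are
    defined. Independent Gaussian noise (fraction of the 16-bit range) is
    added to each tile. Raises :class:`ParameterError` if either tile does
    not fit inside the texture at the requested displacement.
    """
    dx, dy = int(offset[0]), int(offset[1])
    h, w = texture.shape
    ax, ay = max(0, -dx), max(0, -dy)
    bx, by = ax + dx, ay + dy
    for (x0, y0), label in (((ax, ay), "A"), ((bx, by), "B")):
        if x0 < 0 or y0 < 0 or x0 + tile_size > w or y0 + tile_size > h:
            raise ParameterError(
                f"tile {label} at offset ({dx}, {dy}) does not fit inside a "
                f"{w}x{h} texture with tile_size {tile_size}")
    tile_a = texture[ay:ay + tile_size, ax:ax + tile_size].astype(float)
    tile_b = texture[by:by + tile_size, bx:bx + tile_size].astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tile_a = tile_a + rng.normal(0, noise_sd * U16_MAX, tile_a.shape)
        tile_b = tile_b + rng.normal(0, noise_sd * U16_MAX, tile_b.shape)
    return tile_a, tile_b, (dx, dy)


def gen_tile_grid(rows: int, cols: int, tile_size: int = 256,
                  overlap_fraction: Optional[float] = None,
                  jitter: int = 0, seed: int = 0,
                  correlation_length: float = 4.0) -> GroundTruthGrid:
    """Generate a rows x cols tile grid cut from one shared texture.

    Adjacent tiles overlap by ``overlap_fraction * tile_size`` pixels, plus
    an integer jitter drawn uniformly from ``[-jitter, jitter]`` per tile
    and axis. When ``overlap_fraction`` is omitted it is drawn uniformly
    from the acquisition-typical 5-8% window.
    """
    if rows < 1 or cols < 1:
        raise ParameterError("grid must be at least 1x1")
    rng = np.random.default_rng(seed)
    if overlap_fraction is None:
        overlap_fraction = float(rng.uniform(0.05, 0.08))
    overlap_px = int(round(overlap_fraction * tile_size))
    if overlap_px - jitter <= 0 and (rows > 1 or cols > 1):
        raise ParameterError(
            f"overlap {overlap_px} px with jitter {jitter} px leaves adjacent "
            "tiles without guaranteed overlap")
    step = tile_size - overlap_px
    positions = []
    for r in range(rows):
        for c in range(cols):
            jx = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            jy = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            if r == 0 and c == 0:
                jx = jy = 0  # anchor the first tile
            positions.append((c * step + jx, r * step + jy))
    if len(set(positions)) != len(positions):
        # jitter collisions are only possible for pathological parameters
        raise ParameterError("jitter produced duplicate tile positions")
    min_x = min(p[0] for p in positions)
    min_y = min(p[1] for p in positions)
    positions = [(x - min_x, y - min_y) for x, y in positions]
    max_x = max(p[0] for p in positions) + tile_size
    max_y = max(p[1] for p in positions) + tile_size
    texture = gen_texture(TextureSpec(max_x, max_y,
                                      correlation_length=correlation_length,
                                      seed=seed))
    tiles = [texture[y:y + tile_size, x:x + tile_size].astype(float)
             for x, y in positions]
    return GroundTruthGrid(tiles, positions, (rows, cols), tile_size,
                           overlap_fraction, texture)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / (np.linalg.norm(v) + 1e-30)


def _grow_path(skel: Skeleton, start_id: int, n_steps: int, step: float,
               lo: np.ndarray, hi: np.ndarray, rng, branch_id: int,
               turn_sd: float = 0.12,
               initial_direction: Optional[np.ndarray] = None) -> None:
    """Grow a persistent random walk of ``n_steps`` edges from a node.

    Every edge has length exactly ``step``; the direction performs a
    smoothed random walk and reflects off the bounding box, so spacing is
    preserved while staying inside the declared volume.
    """
    if initial_direction is not None:
        direction = _unit(np.asarray(initial_direction, float))
    else:
        direction = _unit(rng.standard_normal(3))
    cur = start_id
    for _ in range(n_steps):
        direction = _unit(direction + turn_sd * rng.standard_normal(3))
        pos = skel.nodes[cur].position + step * direction
        for ax in range(3):
            if pos[ax] < lo[ax] or pos[ax] > hi[ax]:
                direction[ax] = -direction[ax]
                pos = skel.nodes[cur].position + step * direction
        node = skel.new_node(pos)
        node.extra["branch"] = str(branch_id)
        skel.add_edge(cur, node.node_id)
        cur = node.node_id


def gen_skeleton(n_branch_points: int, volume: Sequence[float] = (40000, 40000, 40000),
                 step: float = 100.0, seed: int = 0,
                 trunk_steps: int = 100) -> Skeleton:
    """Generate a random branching tree inside a box, positions in nm.

    The trunk is a persistent random walk of ``trunk_steps`` edges of length
    exactly ``step``; each of ``n_branch_points`` side branches (30-60% of
    the trunk length) sprouts from a random interior trunk node. With
    ``n_branch_points=0`` the result is a simple path. The walk's direction
    persistence (a few micrometres) mimics the local smoothness of real
    neurites, keeping distinct branches well separated relative to a
    typical consensus clique radius.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    volume = np.asarray(volume, float)
    if np.any(volume <= 0):
        raise ParameterError("volume box must be non-degenerate")
    rng = np.random.default_rng(seed)
    lo, hi = np.zeros(3), volume
    skel = Skeleton(name="ground_truth")
    root = skel.add_node(SkeletonNode(1, volume / 2))
    root.extra["branch"] = "0"
    _grow_path(skel, root.node_id, trunk_steps, step, lo, hi, rng, branch_id=0)
    trunk_ids = sorted(skel.nodes)
    for b in range(1, n_branch_points + 1):
        origin = int(rng.choice(trunk_ids[1:-1]))
        n_steps = int(rng.integers(int(0.3 * trunk_steps), int(0.6 * trunk_steps) + 1))
        # branches leave roughly perpendicular to the local trunk tangent,
        # as real collaterals do, so sibling processes separate quickly
        tangent = _unit(skel.nodes[origin + 1].position
                        - skel.nodes[origin - 1].position)
        d = rng.standard_normal(3)
        d -= (d @ tangent) * tangent
        _grow_path(skel, origin, n_steps, step, lo, hi, rng, branch_id=b,
                   initial_direction=d)
    skel.meta["step"] = step
    return skel


def _truncate_terminal(skel: Skeleton, fraction: float, rng) -> None:
    """Remove the terminal subtree whose length best matches the target.

    The tree is rooted at node 1; every node's downstream subtree length is
    computed, and the subtree (including its attaching edge) closest to
    ``fraction`` of the total path length is deleted — one clean cut, as
    when a tracer stops following a process early. The removed length and
    the cut position are recorded in ``meta`` for test bookkeeping.
    """
    total = skel.total_length()
    target = fraction * total
    adj = skel.adjacency()
    # orient the tree away from the root by BFS
    parent = {1: None}
    order = [1]
    for nid in order:
        for m in adj[nid]:
            if m not in parent:
                parent[m] = nid
                order.append(m)
    sub_len = {nid: 0.0 for nid in skel.nodes}
    for nid in reversed(order):
        p = parent[nid]
        if p is not None:
            edge = float(np.linalg.norm(skel.nodes[nid].position
                                        - skel.nodes[p].position))
            sub_len[p] += sub_len[nid] + edge
    # removing node v takes sub_len[v] plus the parent edge
    best, best_err = None, np.inf
    for nid in order[1:]:
        edge = float(np.linalg.norm(skel.nodes[nid].position
                                    - skel.nodes[parent[nid]].position))
        err = abs(sub_len[nid] + edge - target)
        if err < best_err:
            best, best_err = nid, err
    if best is None:
        return
    removed = sub_len[best] + float(np.linalg.norm(
        skel.nodes[best].position - skel.nodes[parent[best]].position))
    cut_pos = skel.nodes[parent[best]].position.copy()
    drop = [best]
    i = 0
    while i < len(drop):
        for m in adj[drop[i]]:
            if m != parent[drop[i]] and m in skel.nodes and m not in drop:
                if parent.get(m) == drop[i]:
                    drop.append(m)
        i += 1
    for nid in drop:
        skel.remove_node(nid)
    skel.meta["truncated_length"] = removed
    skel.meta["truncation_position"] = cut_pos


def perturb_skeleton(skel: Skeleton, spec: PerturbationSpec) -> Skeleton:
    """Apply the tracer-error model to a copy of a skeleton (positions nm).

    Order of operations: truncate a terminal subtree, graft spurious
    branches, then jitter every node position i.i.d. Gaussian. Grafted
    nodes carry the comment ``"graft"`` and the graft origin positions are
    stored in ``meta["graft_origins"]`` so tests can audit them; an
    all-zero spec returns an identical copy.
    """
    rng = np.random.default_rng(spec.seed)
    out = skel.copy()
    out.meta.pop("truncation_position", None)
    if spec.truncate_fraction > 0:
        _truncate_terminal(out, spec.truncate_fraction, rng)
    if spec.graft_count > 0 and spec.graft_length > 0:
        step = float(skel.meta.get("step", 100.0))
        origins = []
        host_ids = sorted(out.nodes)
        for _ in range(spec.graft_count):
            host = int(rng.choice(host_ids))
            origins.append(out.nodes[host].position.copy())
            n_steps = max(1, int(round(spec.graft_length / step)))
            seg = spec.graft_length / n_steps
            direction = _unit(rng.standard_normal(3))
            cur = host
            for _ in range(n_steps):
                direction = _unit(direction + 0.2 * rng.standard_normal(3))
                node = out.new_node(out.nodes[cur].position + seg * direction,
                                    comment="graft")
                out.add_edge(cur, node.node_id)
                cur = node.node_id
        out.meta["graft_origins"] = origins
    if spec.jitter_sd > 0:
        for n in out.nodes.values():
            n.position = n.position + rng.normal(0, spec.jitter_sd, 3)
    return out


def gen_convex_region(center: Sequence[float], radius: float,
                      n_points: int = 20, seed: int = 0) -> np.ndarray:
    """Sample a convex-region point set on a sphere around ``center`` (nm).

    The first four points form a regular tetrahedron at the full radius,
    which guarantees a non-degenerate hull that contains the center; the
    remaining points are drawn uniformly on the sphere surface.
    """
    if n_points < 4:
        raise ParameterError("a 3-D convex region needs at least 4 points")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    center = np.asarray(center, float)
    rng = np.random.default_rng(seed)
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                   dtype=float) / np.sqrt(3)
    dirs = [tet]
    if n_points > 4:
        extra = rng.standard_normal((n_points - 4, 3))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        dirs.append(extra)
    return center + radius * np.concatenate(dirs, axis=0)
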