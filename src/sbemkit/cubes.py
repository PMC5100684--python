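"""Chunked multi-resolution volume store ("cubed" dataset).

The stack is split into fixed-edge 8-bit cubes (default 128 voxels/edge),
one raw file per cube, laid out as ``level{l}/x{cx:04d}/y{cy:04d}/
z{cz:04d}/cube.raw`` with x the fastest-varying axis, plus a plain-text
``.conf`` file describing the geometry. Higher zoom levels are built by
factor-2 mean pooling. A neighborhood loader with an LRU memory budget and
a write-through disk cache models the dynamic data loading used when
browsing: all cubes intersecting a 320-576 voxel box around the focal
point are made resident, at the current zoom level and its neighbors, and
any cube fetched once from the backing source is kept on disk permanently.

Conventions: voxel indices are 0-based; a voxel's nm position is
``index * voxel_size`` (corner convention) with the anisotropic default
pitch (9.25, 9.25, 25) nm. In-memory arrays are indexed ``[z, y, x]``
while API coordinates are ``(x, y, z)`` tuples.
"""

from __future__ import annotations

import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .errors import FetchError, ParameterError
from .skeleton import DEFAULT_SCALE

__all__ = [
    "StackGeometry", "CubeAddress", "NeighborhoodSpec", "CacheState",
    "CubeStore", "build_cubes", "build_pyramid", "read_subvolume",
    "load_neighborhood", "reslice_plane", "LocalSource",
]


@dataclass
class StackGeometry:
    dimensions: Tuple[int, int, int]                 # (nx, ny, nz), level 0
    voxel_size: Tuple[float, float, float] = DEFAULT_SCALE  # nm per axis
    n_levels: int = 1
    cube_edge: int = 128
    name: str = "stack"

    def __post_init__(self):
        if min(self.dimensions) < 1 or self.cube_edge < 1 or self.n_levels < 1:
            raise ParameterError("geometry fields must be positive")
        if min(self.voxel_size) <= 0:
            raise ParameterError("voxel size must be positive")

    def level_dims(self, level: int) -> Tuple[int, int, int]:
        if not 0 <= level < self.n_levels:
            raise ParameterError(f"level {level} does not exist "
                                 f"(store has {self.n_levels})")
        return tuple(-(-d // (1 << level)) for d in self.dimensions)

    def cube_grid(self, level: int) -> Tuple[int, int, int]:
        return tuple(-(-d // self.cube_edge) for d in self.level_dims(level))


class CubeAddress(NamedTuple):
    cx: int
    cy: int
    cz: int
    level: int = 0


@dataclass
class NeighborhoodSpec:
    """Box of ``extent`` voxels per axis around ``focal_point`` (level-0
    voxel coordinates), loaded at each level in ``levels`` after rescaling
    the focal point. Typical extents are 320-576 voxels."""

    focal_point: Tuple[float, float, float]
    extent: Union[int, Tuple[int, int, int]] = 448
    levels: Sequence[int] = (0,)

    def extent3(self) -> Tuple[int, int, int]:
        e = self.extent
        return (e, e, e) if np.isscalar(e) else tuple(e)


class LocalSource:
    """Backing source reading cubes from a cube-store directory."""

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)
        self.fetch_count = 0

    def fetch(self, addr: CubeAddress, geometry: StackGeometry) -> bytes:
        path = _cube_path(self.root, addr)
        self.fetch_count += 1
        if not path.exists():
            raise FetchError(f"cube {addr} not available at {path}")
        return path.read_bytes()


@dataclass
class CacheState:
    """Hybrid cache: every fetched cube persists on disk; an LRU set of
    cubes additionally counts toward the in-memory budget."""

    disk_cache_root: Path
    memory_budget: int                     # bytes
    source: Optional[LocalSource] = None
    resident_cubes: "OrderedDict[CubeAddress, int]" = field(
        default_factory=OrderedDict)

    def __post_init__(self):
        self.disk_cache_root = Path(self.disk_cache_root)

    @property
    def memory_used(self) -> int:
        return sum(self.resident_cubes.values())


def _cube_path(root: Path, addr: CubeAddress) -> Path:
    return (Path(root) / f"level{addr.level}" / f"x{addr.cx:04d}"
            / f"y{addr.cy:04d}" / f"z{addr.cz:04d}" / "cube.raw")


class CubeStore:
    """A cubed dataset rooted at a directory."""

    def __init__(self, root: Union[str, Path], geometry: StackGeometry):
        self.root = Path(root)
        self.geometry = geometry

    # -- configuration file --------------------------------------------
    @property
    def conf_path(self) -> Path:
        return self.root / f"{self.geometry.name}.conf"

    def write_conf(self) -> None:
        g = self.geometry
        lines = [
            f"name={g.name}",
            f"cube_edge={g.cube_edge}",
            f"scale_x={g.voxel_size[0]}",
            f"scale_y={g.voxel_size[1]}",
            f"scale_z={g.voxel_size[2]}",
            f"dims_x={g.dimensions[0]}",
            f"dims_y={g.dimensions[1]}",
            f"dims_z={g.dimensions[2]}",
            f"levels={g.n_levels}",
        ]
        self.root.mkdir(parents=True, exist_ok=True)
        self.conf_path.write_text("\n".join(lines) + "\n")

    @classmethod
    def open(cls, root: Union[str, Path]) -> "CubeStore":
        root = Path(root)
        confs = sorted(root.glob("*.conf"))
        if not confs:
            raise ParameterError(f"no .conf file under {root}")
        kv = {}
        for line in confs[0].read_text().splitlines():
            line = line.strip()
            if line and "=" in line:
                k, v = line.split("=", 1)
                kv[k.strip()] = v.strip()
        geom = StackGeometry(
            dimensions=(int(kv["dims_x"]), int(kv["dims_y"]), int(kv["dims_z"])),
            voxel_size=(float(kv["scale_x"]), float(kv["scale_y"]),
                        float(kv["scale_z"])),
            n_levels=int(kv.get("levels", 1)),
            cube_edge=int(kv.get("cube_edge", 128)),
            name=kv.get("name", "stack"),
        )
        return cls(root, geom)

    # -- cube level I/O -------------------------------------------------
    def cube_path(self, addr: CubeAddress) -> Path:
        return _cube_path(self.root, addr)

    def write_cube(self, addr: CubeAddress, data: np.ndarray) -> None:
        e = self.geometry.cube_edge
        if data.shape != (e, e, e) or data.dtype != np.uint8:
            raise ParameterError(f"cube data must be uint8 of shape ({e},{e},{e})")
        path = self.cube_path(addr)
        path.parent.mkdir(parents=True, exist_ok=True)
        data.tofile(path)

    def read_cube(self, addr: CubeAddress) -> np.ndarray:
        e = self.geometry.cube_edge
        path = self.cube_path(addr)
        if not path.exists():
            return np.zeros((e, e, e), dtype=np.uint8)
        return np.fromfile(path, dtype=np.uint8).reshape(e, e, e)

    # -- subvolume access ------------------------------------------------
    def read_subvolume(self, origin: Sequence[int], shape: Sequence[int],
                       level: int = 0) -> np.ndarray:
        return read_subvolume(self, origin, shape, level)

    def read_level(self, level: int = 0) -> np.ndarray:
        return read_subvolume(self, (0, 0, 0), self.geometry.level_dims(level),
                              level)


def build_cubes(source: Union[np.ndarray, Iterable[np.ndarray]],
                geometry: StackGeometry, root: Union[str, Path]) -> CubeStore:
    """Cube a volume (3-D ``[z, y, x]`` array or a stream of 2-D sections).

    All level-0 cube files are written, with partial boundary cubes
    zero-padded to the full edge, and the dataset ``.conf`` file is
    emitted. Input must be 8-bit (normalize contrast first otherwise).
    """
    nx, ny, nz = geometry.dimensions
    e = geometry.cube_edge
    store = CubeStore(root, geometry)
    store.write_conf()
    if isinstance(source, np.ndarray):
        if source.dtype != np.uint8:
            raise ParameterError("volume must be uint8; apply contrast "
                                 "normalization first")
        if source.shape != (nz, ny, nx):
            raise ParameterError(f"volume shape {source.shape} does not match "
                                 f"geometry (z,y,x)=({nz},{ny},{nx})")
        sections: Iterable[np.ndarray] = (source[z] for z in range(nz))
    else:
        sections = source

    gx, gy, gz = geometry.cube_grid(0)
    slab = np.zeros((e, ny, nx), dtype=np.uint8)
    z_written = 0
    zi = 0

    def flush(cz: int, used: int):
        if used < e:
            slab[used:] = 0
        for cy in range(gy):
            for cx in range(gx):
                cube = np.zeros((e, e, e), dtype=np.uint8)
                ys, xs = cy * e, cx * e
                block = slab[:, ys:ys + e, xs:xs + e]
                cube[:, :block.shape[1], :block.shape[2]] = block
                store.write_cube(CubeAddress(cx, cy, cz, 0), cube)

    for z, sec in enumerate(sections):
        sec = np.asarray(sec)
        if sec.dtype != np.uint8:
            raise ParameterError(f"section {z} is not uint8")
        if sec.shape != (ny, nx):
            raise ParameterError(f"section {z} has shape {sec.shape}, "
                                 f"expected ({ny}, {nx})")
        slab[zi] = sec
        zi += 1
        z_written += 1
        if zi == e:
            flush(z_written // e - 1, e)
            zi = 0
    if z_written != nz:
        raise ParameterError(f"got {z_written} sections, geometry says {nz}")
    if zi:
        flush(gz - 1, zi)
    return store


def _pool2(arr: np.ndarray) -> np.ndarray:
    """Factor-2 mean pooling per axis with ceil semantics.

    Odd trailing samples are edge-replicated before pooling, which equals
    averaging over the voxels actually present. Rounded half-up to uint8.
    """
    pads = [(0, d % 2) for d in arr.shape]
    a = np.pad(arr.astype(np.float64), pads, mode="edge")
    z, y, x = a.shape
    a = a.reshape(z // 2, 2, y // 2, 2, x // 2, 2).mean(axis=(1, 3, 5))
    return np.floor(a + 0.5).astype(np.uint8)


def build_pyramid(store: CubeStore, n_levels: int) -> CubeStore:
    """Add zoom levels 1..n_levels-1 by successive 2x2x2 mean pooling."""
    g = store.geometry
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    if (1 << (n_levels - 1)) > min(g.dimensions):
        raise ParameterError(
            f"{n_levels} levels exceed log2 of the smallest dimension "
            f"{min(g.dimensions)}")
    g.n_levels = n_levels
    store.write_conf()
    prev = store.read_level(0)
    for level in range(1, n_levels):
        prev = _pool2(prev)
        dx, dy, dz = g.level_dims(level)
        assert prev.shape == (dz, dy, dx)
        e = g.cube_edge
        gx, gy, gz = g.cube_grid(level)
        for cz in range(gz):
            for cy in range(gy):
                for cx in range(gx):
                    cube = np.zeros((e, e, e), dtype=np.uint8)
                    blk = prev[cz * e:(cz + 1) * e, cy * e:(cy + 1) * e,
                               cx * e:(cx + 1) * e]
                    cube[:blk.shape[0], :blk.shape[1], :blk.shape[2]] = blk
                    store.write_cube(CubeAddress(cx, cy, cz, level), cube)
    return store


def read_subvolume(store: CubeStore, origin: Sequence[int],
                   shape: Sequence[int], level: int = 0) -> np.ndarray:
    """Read an axis-aligned box; voxels outside the stack are 0.

    ``origin``/``shape`` are ``(x, y, z)`` in level voxels; the result is
    indexed ``[z, y, x]``. A box that misses the stack entirely returns
    all zeros with a warning.
    """
    g = store.geometry
    dims = g.level_dims(level)  # validates the level
    ox, oy, oz = (int(v) for v in origin)
    sx, sy, sz = (int(v) for v in shape)
    if min(sx, sy, sz) < 1:
        raise ParameterError("shape must be positive")
    out = np.zeros((sz, sy, sx), dtype=np.uint8)
    lo = [max(0, v) for v in (ox, oy, oz)]
    hi = [min(d, o + s) for d, o, s in zip(dims, (ox, oy, oz), (sx, sy, sz))]
    if any(l >= h for l, h in zip(lo, hi)):
        warnings.warn("requested box lies entirely outside the stack",
                      stacklevel=2)
        return out
    e = g.cube_edge
    for cz in range(lo[2] // e, (hi[2] - 1) // e + 1):
        for cy in range(lo[1] // e, (hi[1] - 1) // e + 1):
            for cx in range(lo[0] // e, (hi[0] - 1) // e + 1):
                cube = store.read_cube(CubeAddress(cx, cy, cz, level))
                x0, y0, z0 = cx * e, cy * e, cz * e
                ax0, ax1 = max(lo[0], x0), min(hi[0], x0 + e)
                ay0, ay1 = max(lo[1], y0), min(hi[1], y0 + e)
                az0, az1 = max(lo[2], z0), min(hi[2], z0 + e)
                out[az0 - oz:az1 - oz, ay0 - oy:ay1 - oy, ax0 - ox:ax1 - ox] = \
                    cube[az0 - z0:az1 - z0, ay0 - y0:ay1 - y0, ax0 - x0:ax1 - x0]
    return out


def cubes_in_neighborhood(geometry: StackGeometry,
                          spec: NeighborhoodSpec) -> List[CubeAddress]:
    """All cube addresses whose boxes intersect the neighborhood box, at
    each requested level (focal point rescaled per level)."""
    out: List[CubeAddress] = []
    e = geometry.cube_edge
    ext = spec.extent3()
    for level in sorted(set(spec.levels)):
        grid = geometry.cube_grid(level)
        focal = [f / (1 << level) for f in spec.focal_point]
        ranges = []
        for ax in range(3):
            lo = focal[ax] - ext[ax] / 2
            hi = focal[ax] + ext[ax] / 2
            c0 = max(0, int(math.floor(lo / e)))
            c1 = min(grid[ax] - 1, int(math.ceil(hi / e)) - 1 if hi % e == 0
                     else int(math.floor(hi / e)))
            ranges.append(range(c0, c1 + 1))
        for cz in ranges[2]:
            for cy in ranges[1]:
                for cx in ranges[0]:
                    out.append(CubeAddress(cx, cy, cz, level))
    return out


def load_neighborhood(geometry: StackGeometry, spec: NeighborhoodSpec,
                      cache: CacheState) -> CacheState:
    """Make all cubes around the focal point resident.

    Cubes already in the disk cache are served from disk without touching
    the backing source ("hybrid" persistence); newly fetched cubes are
    written through to disk. Residency beyond ``memory_budget`` is evicted
    least-recently-used; eviction never deletes the disk copy.
    """
    if cache.source is None:
        raise ParameterError("cache has no backing source configured")
    cube_bytes = geometry.cube_edge ** 3
    for addr in cubes_in_neighborhood(geometry, spec):
        disk = _cube_path(cache.disk_cache_root, addr)
        if not disk.exists():
            data = cache.source.fetch(addr, geometry)
            disk.parent.mkdir(parents=True, exist_ok=True)
            disk.write_bytes(data)
        # touch for LRU order
        cache.resident_cubes.pop(addr, None)
        cache.resident_cubes[addr] = cube_bytes
    while cache.memory_used > cache.memory_budget and cache.resident_cubes:
        cache.resident_cubes.popitem(last=False)
    return cache


def reslice_plane(store: CubeStore, center: Sequence[float],
                  u: Sequence[float], v: Sequence[float],
                  out_shape: Tuple[int, int], pixel_pitch: float,
                  level: int = 0) -> np.ndarray:
    """Trilinear reslice on an arbitrarily oriented plane.

    ``center`` is in nm, ``u``/``v`` are orthonormal nm-space direction
    vectors, and output pixel ``(i, j)`` samples the volume at
    ``center + (i - ci) * pitch * u + (j - cj) * pitch * v`` with
    ``ci = (rows - 1) / 2`` (and likewise ``cj``). nm positions map to
    voxel indices through the anisotropic voxel size; samples outside the
    stack are 0.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if (abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9
            or abs(float(u @ v)) > 1e-9):
        raise ParameterError("u and v must be orthonormal")
    g = store.geometry
    dims = g.level_dims(level)
    vox = np.asarray(g.voxel_size, float) * (1 << level)  # nm per level voxel
    ni, nj = out_shape
    ci, cj = (ni - 1) / 2.0, (nj - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    pts = (np.asarray(center, float)[None, None, :]
           + (ii - ci)[..., None] * pixel_pitch * u[None, None, :]
           + (jj - cj)[..., None] * pixel_pitch * v[None, None, :])
    coords_xyz = pts / vox[None, None, :]  # fractional voxel indices
    # bounding subvolume covering all sample points (clipped to the stack)
    lo = np.maximum(np.floor(coords_xyz.reshape(-1, 3).min(axis=0)) - 1, 0)
    hi = np.minimum(np.ceil(coords_xyz.reshape(-1, 3).max(axis=0)) + 2,
                    np.asarray(dims, float))
    if np.any(lo >= hi):
        return np.zeros(out_shape, dtype=float)
    origin = lo.astype(int)
    shape = (hi - lo).astype(int)
    sub = read_subvolume(store, origin, shape, level).astype(float)
    local = np.stack([coords_xyz[..., 2] - origin[2],   # z
                      coords_xyz[..., 1] - origin[1],   # y
                      coords_xyz[..., 0] - origin[0]])  # x
    return ndimage.map_coordinates(sub, local, order=1,
                                   mode="constant", cval=0.0)
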