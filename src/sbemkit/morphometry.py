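"""Convex-region geometry, innervation accounting and accuracy metrics.

Glomeruli are represented as convex hulls of manually placed 3-D points;
the neurite length a neuron contributes to a region is the exact length of
its skeleton edges clipped against the hull's half-spaces. The per-neuron,
per-region lengths form the innervation table, whose row-wise argmax
defines each neuron's parent glomerulus. Reconstruction accuracy against a
reference skeleton is quantified by length-based recall (missed
processes), precision (wrongly traced processes) and the relative length
error combining both, at a configurable distance tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import GeometryError, ParameterError
from .nml import CELL_TYPES, InnervationTable
from .skeleton import Skeleton

__all__ = [
    "ConvexRegion", "ErrorMetrics", "ParentAssignment",
    "build_hull", "clip_segment", "neurite_length_in_region",
    "build_innervation_table", "parent_glomerulus", "reconstruction_metrics",
]


@dataclass
class ConvexRegion:
    """A convex region (e.g. one glomerulus) in nm coordinates."""

    region_id: str
    vertices: np.ndarray          # the input points (n, 3)
    hull: ConvexHull
    group: str = ""

    @property
    def volume(self) -> float:
        return float(self.hull.volume)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        pts = np.atleast_2d(points)
        eq = self.hull.equations  # A x + b <= 0 inside
        return np.all(pts @ eq[:, :3].T + eq[:, 3] <= tol, axis=1)


class ErrorMetrics(NamedTuple):
    recall: float
    precision: float
    relative_length_error: float
    tolerance: float


class ParentAssignment(NamedTuple):
    region_id: Optional[str]
    tied: bool


def build_hull(points: np.ndarray, region_id: str = "",
               group: str = "") -> ConvexRegion:
    """Convex hull of >= 4 non-coplanar 3-D points (nm)."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise GeometryError("need at least 4 three-dimensional points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate point set: {exc}") from exc
    return ConvexRegion(region_id=region_id, vertices=pts, hull=hull,
                        group=group)


def clip_segment(region: ConvexRegion, p: Sequence[float],
                 q: Sequence[float]) -> float:
    """Exact length (nm) of the segment p->q inside the region.

    The segment is clipped against every hull half-space, intersecting the
    parameter intervals; disjoint segments contribute 0. Additive: splitting
    a segment at any interior point leaves the summed result unchanged.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    eq = region.hull.equations
    a = eq[:, :3] @ d            # rate of change of each constraint along t
    b = eq[:, :3] @ p + eq[:, 3]  # constraint value at t=0 (<=0 inside)
    t0, t1 = 0.0, 1.0
    for ai, bi in zip(a, b):
        if abs(ai) < 1e-300:
            if bi > 0:
                return 0.0
            continue
        t_hit = -bi / ai
        if ai > 0:
            t1 = min(t1, t_hit)
        else:
            t0 = max(t0, t_hit)
        if t0 >= t1:
            return 0.0
    return float((t1 - t0) * np.linalg.norm(d))


def neurite_length_in_region(skeleton: Skeleton, region: ConvexRegion,
                             scale: Optional[Sequence[float]] = None) -> float:
    """Neurite path length of a skeleton inside a region, in micrometres.

    ``scale`` converts skeleton positions to nm (per-axis voxel pitch); pass
    ``(1, 1, 1)`` for skeletons already in nm. Falls back to the skeleton's
    ``meta["scale"]``; with neither, an error is raised.
    """
    if scale is None:
        scale = skeleton.meta.get("scale")
    if scale is None:
        raise ParameterError("no nm scale known for this skeleton; pass "
                             "scale explicitly (e.g. (9.25, 9.25, 25))")
    s = np.asarray(scale, float)
    total = 0.0
    for a, b in skeleton.edges:
        total += clip_segment(region, skeleton.nodes[a].position * s,
                              skeleton.nodes[b].position * s)
    return total / 1000.0


def build_innervation_table(skeletons: Dict[int, Skeleton],
                            regions: Sequence[ConvexRegion],
                            cell_types: Dict[int, str],
                            scale: Optional[Sequence[float]] = None
                            ) -> InnervationTable:
    """Neurite length (um) of every neuron in every region, plus cell type.

    Neurons missing from ``cell_types`` (or carrying an unknown label) are
    typed ``"other"`` with a warning.
    """
    ids = sorted(skeletons)
    region_ids = [r.region_id for r in regions]
    if len(set(region_ids)) != len(region_ids):
        raise ParameterError("region ids must be unique")
    rows = []
    unknown = []
    for nid in ids:
        ct = cell_types.get(nid)
        if ct not in CELL_TYPES:
            if ct is not None or nid not in cell_types:
                unknown.append(nid)
            ct = "other"
        row = {"neuron_id": nid, "cell_type": ct}
        for r in regions:
            row[r.region_id] = neurite_length_in_region(skeletons[nid], r,
                                                        scale=scale)
        rows.append(row)
    if unknown:
        warnings.warn(f"neuron(s) {unknown} have no valid cell type; "
                      "labelled 'other'", stacklevel=2)
    df = pd.DataFrame(rows, columns=["neuron_id", "cell_type"] + region_ids)
    return InnervationTable(df)


def parent_glomerulus(row: pd.Series) -> ParentAssignment:
    """Region with the longest neurite length in a table row.

    Ties are broken lexicographically (and flagged); an all-zero row is
    unassigned.
    """
    lengths = {k: float(v) for k, v in row.items()
               if k not in ("neuron_id", "cell_type")}
    if not lengths or max(lengths.values()) <= 0:
        return ParentAssignment(None, False)
    best = max(lengths.values())
    winners = sorted(k for k, v in lengths.items() if v == best)
    return ParentAssignment(winners[0], len(winners) > 1)


def _dense_samples(skeleton: Skeleton, spacing: float
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Sample points along every edge at most ``spacing`` apart, each
    weighted by the arc length it represents."""
    pts, wts = [], []
    for a, b in sorted(skeleton.edges):
        pa = skeleton.nodes[a].position
        pb = skeleton.nodes[b].position
        L = float(np.linalg.norm(pb - pa))
        n = max(1, int(np.ceil(L / spacing)))
        # midpoints of n equal pieces: weights sum exactly to L
        t = (np.arange(n) + 0.5) / n
        pts.append(pa[None, :] + t[:, None] * (pb - pa)[None, :])
        wts.append(np.full(n, L / n))
    if not pts:
        # a single isolated node still counts as zero length
        return np.zeros((0, 3)), np.zeros(0)
    return np.concatenate(pts), np.concatenate(wts)


def _covered_fraction(samples: np.ndarray, weights: np.ndarray,
                      other: Skeleton, tolerance: float,
                      spacing: float) -> float:
    """Weighted fraction of samples within ``tolerance`` of the other
    skeleton (approximated by its own dense sampling)."""
    ref, _ = _dense_samples(other, spacing)
    if len(ref) == 0:
        ref = other.positions()
    tree = cKDTree(ref)
    d, _ = tree.query(samples)
    total = weights.sum()
    if total == 0:
        return 1.0
    return float(weights[d <= tolerance].sum() / total)


def reconstruction_metrics(test: Skeleton, truth: Skeleton,
                           tolerance: float = 100.0) -> ErrorMetrics:
    """Length-based recall, precision and relative length error (nm frame).

    Both skeletons are densely resampled at ``tolerance / 4``. Recall is
    the fraction of truth arc length lying within ``tolerance`` of the test
    skeleton (1 - recall measures missed processes); precision is the
    fraction of test arc length within tolerance of the truth (1 -
    precision measures wrongly traced processes); the relative length
    error is (missed truth length + excess test length) / total truth
    length. Swapping test and truth swaps recall and precision exactly.
    """
    if len(test.nodes) == 0 or len(truth.nodes) == 0:
        raise ParameterError("both skeletons must be non-empty")
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    spacing = tolerance / 4.0
    truth_pts, truth_w = _dense_samples(truth, spacing)
    test_pts, test_w = _dense_samples(test, spacing)
    truth_len = truth_w.sum()
    test_len = test_w.sum()
    if truth_len == 0 or test_len == 0:
        raise ParameterError("skeletons must have non-zero length")
    recall = _covered_fraction(truth_pts, truth_w, test, tolerance, spacing)
    precision = _covered_fraction(test_pts, test_w, truth, tolerance, spacing)
    missed = (1.0 - recall) * truth_len
    excess = (1.0 - precision) * test_len
    return ErrorMetrics(recall=recall, precision=precision,
                        relative_length_error=float((missed + excess) / truth_len),
                        tolerance=tolerance)
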