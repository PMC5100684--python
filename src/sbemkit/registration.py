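"""Per-section tile mosaicking.

The pipeline mirrors a translational SBEM stitching workflow: tile images
are standardized column-wise then row-wise, pairwise integer offsets are
found at the peak of the FFT cross-correlogram restricted to a central
window (default +/-256 px, the maximal expected overlap displacement), the
per-tile mosaic positions are solved globally in a least-squares
displacement sense with one anchor tile fixing the gauge, intensities are
mapped to 8 bit by a Gaussian histogram fit thresholded at k standard
deviations (k in [1.5, 3]), and the mosaic is assembled.

Only translations are modeled: small tile sizes and conductive embedding
keep distortions negligible, so no elastic registration is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal, sparse
from scipy.sparse import linalg as sparse_linalg

from .errors import DisconnectedGraphError, NoSignalError, ParameterError

__all__ = [
    "Tile", "OffsetEstimate", "SectionLayout", "ContrastModel",
    "standardize", "estimate_offset", "solve_layout",
    "fit_contrast", "normalize_contrast", "stitch",
]


@dataclass
class Tile:
    image: np.ndarray
    grid_index: Tuple[int, int] = (0, 0)
    nominal_position: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ParameterError("tile image must be a non-empty 2-D raster")


@dataclass(frozen=True)
class OffsetEstimate:
    """Integer displacement of tile ``pair[1]`` relative to ``pair[0]``."""

    dx: int
    dy: int
    peak_score: float
    pair: Tuple[Hashable, Hashable]


@dataclass
class SectionLayout:
    positions: Dict[Hashable, Tuple[float, float]]
    anchor_tile: Hashable
    residuals: Dict[Tuple[Hashable, Hashable], float] = field(default_factory=dict)


@dataclass
class ContrastModel:
    peak: float
    sigma: float
    k: float = 2.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if not (1.5 <= self.k <= 3.0):
            warnings.warn(f"threshold multiplier k={self.k} outside the "
                          "usual [1.5, 3] range", stacklevel=2)


def standardize(image: np.ndarray) -> np.ndarray:
    """Standardize columns (zero mean, unit sd), then rows.

    Zero-variance columns/rows are set to all zeros with a warning instead
    of raising, so blank tile margins do not abort a batch.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ParameterError("image must be 2-D with at least 2 rows and columns")
    out = img.copy()
    for axis, label in ((0, "column"), (1, "row")):
        mean = out.mean(axis=axis, keepdims=True)
        sd = out.std(axis=axis, keepdims=True)
        flat = (sd == 0)
        if flat.any():
            warnings.warn(f"{int(flat.sum())} zero-variance {label}(s) set to "
                          "zeros during standardization", stacklevel=2)
            sd = np.where(flat, 1.0, sd)
        out = (out - mean) / sd
        out[np.broadcast_to(flat, out.shape)] = 0.0
    return out


def _ncc_correlogram(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation over every lag's actual overlap window.

    ``out[h-1+sy, w-1+sx]`` is the Pearson correlation of ``a`` and ``b``
    restricted to the pixels where they overlap at lag ``(sx, sy)``, so the
    statistic is unbiased for thin overlap strips. Lags whose overlap is
    below ``max(64, 0.5%)`` of the image area, or where either window is
    flat, score ``-inf``. All sums are Fourier-domain correlations, so the
    result equals the direct spatial computation to rounding error.
    """
    h, w = a.shape
    ones = np.ones_like(a)

    def xcorr(x, y):
        return signal.fftconvolve(x, y[::-1, ::-1], mode="full")

    n_ov = np.outer(h - np.abs(np.arange(-(h - 1), h), dtype=float),
                    w - np.abs(np.arange(-(w - 1), w), dtype=float))
    sum_ab = xcorr(a, b)
    sum_a = xcorr(a, ones)
    sum_b = xcorr(ones, b)
    sum_a2 = xcorr(a * a, ones)
    sum_b2 = xcorr(ones, b * b)
    cov = sum_ab - sum_a * sum_b / n_ov
    var_a = np.maximum(sum_a2 - sum_a ** 2 / n_ov, 0.0)
    var_b = np.maximum(sum_b2 - sum_b ** 2 / n_ov, 0.0)
    denom = np.sqrt(var_a * var_b)
    floor = max(64.0, 0.005 * h * w)
    eps = 1e-8 * h * w
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((n_ov >= floor) & (denom > eps), cov / denom, -np.inf)
    return out


def estimate_offset(image_a: np.ndarray, image_b: np.ndarray,
                    max_offset: int = 256,
                    nominal: Tuple[int, int] = (0, 0)) -> OffsetEstimate:
    """Integer translational offset of ``image_b`` relative to ``image_a``.

    Both images are standardized, their cross-correlogram (normalized per
    overlap window, see :func:`_ncc_correlogram`) is computed in the
    Fourier domain, and the peak is searched only inside a
    ``[-max_offset, max_offset]^2`` window around ``nominal`` — the maximal
    expected displacement between overlapping image parts. The returned
    ``(dx, dy)`` is the mosaic position of B relative to A, i.e. with
    ``B[y, x] == A[y + dy, x + dx]`` the estimate is exactly ``(dx, dy)``.
    Ties are broken by the displacement closest to nominal, then
    lexicographically by ``(dx, dy)``.
    """
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    if a.shape != b.shape:
        raise ParameterError(f"image shapes differ: {a.shape} vs {b.shape}")
    if max_offset < 1 or max_offset >= min(a.shape) / 2 + 1:
        raise ParameterError("max_offset must satisfy 1 <= max_offset < min(dims)/2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sa = standardize(a)
        sb = standardize(b)
    if not sa.any() or not sb.any():
        raise NoSignalError("image is constant after standardization")
    # the correlogram normalizes per overlap window, so it is fed the raw
    # images; the standardized copies above only gate the no-signal case
    corr = _ncc_correlogram(a, b)
    h, w = a.shape
    cy, cx = h - 1, w - 1
    nx, ny = int(nominal[0]), int(nominal[1])
    x_lo = max(-cx, nx - max_offset)
    x_hi = min(cx, nx + max_offset)
    y_lo = max(-cy, ny - max_offset)
    y_hi = min(cy, ny + max_offset)
    win = corr[cy + y_lo:cy + y_hi + 1, cx + x_lo:cx + x_hi + 1]
    peak = win.max()
    ys, xs = np.nonzero(win >= peak - 1e-9 * abs(peak))
    cands = sorted(zip(xs + x_lo, ys + y_lo),
                   key=lambda d: ((d[0] - nx) ** 2 + (d[1] - ny) ** 2,
                                  d[0], d[1]))
    dx, dy = (int(v) for v in cands[0])
    score = float(win[dy - y_lo, dx - x_lo])
    return OffsetEstimate(dx=dx, dy=dy, peak_score=score, pair=(0, 1))


def solve_layout(offsets: Sequence[OffsetEstimate], n_tiles: int,
                 anchor: Hashable = 0, weighted: bool = False) -> SectionLayout:
    """Globally optimal tile positions from pairwise offsets.

    Minimizes ``sum_pairs || (p_j - p_i) - (dx, dy)_ij ||^2`` per coordinate
    as a sparse linear least-squares problem, with the anchor tile pinned at
    the origin to remove the translational gauge freedom. With
    ``weighted=True`` each pair is weighted by its ``peak_score``.
    Raises :class:`DisconnectedGraphError` (naming the components) if the
    pair graph does not connect every tile to the anchor.
    """
    tile_ids = sorted({anchor} | {t for o in offsets for t in o.pair},
                      key=lambda t: (str(type(t)), t))
    if n_tiles > len(tile_ids):
        tile_ids = sorted(set(tile_ids) | set(range(n_tiles)),
                          key=lambda t: (str(type(t)), t))
    if anchor not in tile_ids:
        raise ParameterError(f"anchor tile {anchor!r} not among tiles")
    index = {t: i for i, t in enumerate(tile_ids)}
    n = len(tile_ids)

    # connectivity check with component listing
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for o in offsets:
        ra, rb = find(index[o.pair[0]]), find(index[o.pair[1]])
        if ra != rb:
            parent[ra] = rb
    roots: Dict[int, list] = {}
    for t, i in index.items():
        roots.setdefault(find(i), []).append(t)
    if len(roots) > 1:
        raise DisconnectedGraphError(list(roots.values()))

    rows, cols, vals = [], [], []
    bx, by, wts = [], [], []
    for r, o in enumerate(offsets):
        i, j = index[o.pair[0]], index[o.pair[1]]
        wgt = float(o.peak_score) if weighted else 1.0
        rows += [r, r]
        cols += [j, i]
        vals += [1.0, -1.0]
        bx.append(o.dx)
        by.append(o.dy)
        wts.append(wgt)
    m = len(offsets)
    # anchor row pins the gauge
    rows.append(m)
    cols.append(index[anchor])
    vals.append(1.0)
    bx.append(0.0)
    by.append(0.0)
    wts.append(1.0)
    sw = np.sqrt(np.asarray(wts))
    A = sparse.csr_matrix((np.asarray(vals) * sw[np.asarray(rows)],
                           (rows, cols)), shape=(m + 1, n))
    if n <= 2000:  # typical sections have tens of tiles; dense solve is exact
        Ad = A.toarray()
        px = np.linalg.lstsq(Ad, np.asarray(bx, float) * sw, rcond=None)[0]
        py = np.linalg.lstsq(Ad, np.asarray(by, float) * sw, rcond=None)[0]
    else:
        px = sparse_linalg.lsqr(A, np.asarray(bx, float) * sw,
                                atol=1e-14, btol=1e-14)[0]
        py = sparse_linalg.lsqr(A, np.asarray(by, float) * sw,
                                atol=1e-14, btol=1e-14)[0]
    # re-anchor exactly
    px -= px[index[anchor]]
    py -= py[index[anchor]]
    positions = {t: (float(px[index[t]]), float(py[index[t]])) for t in tile_ids}
    residuals = {}
    for o in offsets:
        i, j = index[o.pair[0]], index[o.pair[1]]
        residuals[o.pair] = float(np.hypot(px[j] - px[i] - o.dx,
                                           py[j] - py[i] - o.dy))
    return SectionLayout(positions=positions, anchor_tile=anchor,
                         residuals=residuals)


def fit_contrast(image: np.ndarray, k: float = 2.0) -> ContrastModel:
    """Fit a Gaussian to the dominant mode of the intensity histogram.

    The fit is restricted to +/-3 MAD around the histogram mode, which makes
    it robust to dark-structure and bright-particle tails. Raises
    :class:`NoSignalError` for a constant image.
    """
    img = np.asarray(image)
    vals = img.ravel().astype(float)
    if vals.max() == vals.min():
        raise NoSignalError("constant image has no contrast to fit")
    nbins = min(512, max(64, int(vals.max() - vals.min())))
    counts, edges = np.histogram(vals, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # clipped data piles up in the extreme bins; exclude them from the
    # mode search so a saturation spike is never taken for the peak
    interior = counts.copy()
    interior[0] = interior[-1] = 0
    mode = centers[int(np.argmax(interior))]
    mad = np.median(np.abs(vals - np.median(vals))) or vals.std()
    sel = np.abs(centers - mode) <= 3 * mad
    sel[0] = sel[-1] = False  # saturation spikes would skew the fit
    if sel.sum() < 5:
        sel = np.ones(len(centers), dtype=bool)
    x, y = centers[sel], counts[sel].astype(float)

    def gauss(t, amp, mu, sig):
        return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    p0 = (float(y.max()), float(mode), float(max(mad, 1.0)))
    try:
        popt, _ = optimize.curve_fit(gauss, x, y, p0=p0, maxfev=10000)
        amp, mu, sig = popt
        sig = abs(float(sig))
        if sig <= 0 or not np.isfinite(mu):
            raise RuntimeError
    except RuntimeError:
        mu, sig = float(mode), float(max(mad * 1.4826, 1.0))
    return ContrastModel(peak=float(mu), sigma=float(sig), k=float(k))


def normalize_contrast(image: np.ndarray, model: ContrastModel) -> np.ndarray:
    """Linear 16->8 bit map: peak - k*sigma -> 0, peak + k*sigma -> 255.

    Values are clipped to [0, 255] and rounded half-up, so a pixel exactly
    at the fitted peak maps to 128.
    """
    img = np.asarray(image, float)
    lo = model.peak - model.k * model.sigma
    hi = model.peak + model.k * model.sigma
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def stitch(tiles: Sequence[Tile], layout: SectionLayout,
           blend: str = "last") -> Tuple[np.ndarray, np.ndarray]:
    """Assemble tiles into a mosaic according to a layout.

    Returns ``(mosaic, mask)`` where ``mask[y, x]`` is the index (into
    ``tiles``) of the contributing tile, -1 where uncovered. Blend policies:

    ``"last"``
        last-writer-wins; single-coverage pixels are bit-exact copies.
    ``"feather"``
        linear distance-to-edge weighted average in overlaps; the mask
        records the highest-weight contributor.
    """
    if blend not in ("last", "feather"):
        raise ParameterError(f"unknown blend policy {blend!r}")
    ids = sorted(layout.positions)
    if len(tiles) != len(ids):
        raise ParameterError("layout does not cover all tiles")
    pos = [layout.positions[t] for t in ids]
    xs = [int(round(p[0])) for p in pos]
    ys = [int(round(p[1])) for p in pos]
    x0, y0 = min(xs), min(ys)
    x1 = max(x + t.image.shape[1] for x, t in zip(xs, tiles))
    y1 = max(y + t.image.shape[0] for y, t in zip(ys, tiles))
    H, W = y1 - y0, x1 - x0
    mask = np.full((H, W), -1, dtype=int)
    if blend == "last":
        mosaic = np.zeros((H, W), dtype=float)
        for i, t in enumerate(tiles):
            oy, ox = ys[i] - y0, xs[i] - x0
            h, w = t.image.shape
            mosaic[oy:oy + h, ox:ox + w] = t.image
            mask[oy:oy + h, ox:ox + w] = i
        return mosaic.astype(tiles[0].image.dtype), mask

    acc = np.zeros((H, W), dtype=float)
    wacc = np.zeros((H, W), dtype=float)
    wbest = np.zeros((H, W), dtype=float)
    for i, t in enumerate(tiles):
        h, w = t.image.shape
        ry = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1)
        rx = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1)
        wgt = np.minimum.outer(ry, rx).astype(float)
        oy, ox = ys[i] - y0, xs[i] - x0
        acc[oy:oy + h, ox:ox + w] += wgt * t.image
        wacc[oy:oy + h, ox:ox + w] += wgt
        better = wgt > wbest[oy:oy + h, ox:ox + w]
        mask[oy:oy + h, ox:ox + w][better] = i
        wbest[oy:oy + h, ox:ox + w][better] = wgt[better]
    out = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
    return out.astype(tiles[0].image.dtype), mask


def register_grid(tiles: Sequence[Tile], rows: int, cols: int,
                  max_offset: int = 256, anchor: int = 0,
                  overlap_fraction: float = 0.065,
                  log: Optional[list] = None) -> Tuple[List[OffsetEstimate], SectionLayout]:
    """Estimate offsets for all adjacent pairs of a rows x cols grid and
    solve the global layout. Tiles are ordered row-major; the nominal
    displacement between neighbors is derived from ``overlap_fraction``
    (the acquisition aims for 5-8% overlap) and the correlation peak is
    searched within ``max_offset`` of it."""
    if len(tiles) != rows * cols:
        raise ParameterError(f"expected {rows * cols} tiles, got {len(tiles)}")
    offsets = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for (rr, cc) in ((r, c + 1), (r + 1, c)):
                if rr >= rows or cc >= cols:
                    continue
                j = rr * cols + cc
                th, tw = tiles[i].image.shape
                nominal = (int(round((cc - c) * tw * (1 - overlap_fraction))),
                           int(round((rr - r) * th * (1 - overlap_fraction))))
                est = estimate_offset(tiles[i].image, tiles[j].image,
                                      max_offset, nominal=nominal)
                est = OffsetEstimate(est.dx, est.dy, est.peak_score, (i, j))
                offsets.append(est)
                if log is not None:
                    log.append(json.dumps({"pair": [i, j], "dx": est.dx,
                                           "dy": est.dy,
                                           "peak_score": est.peak_score}))
    return offsets, solve_layout(offsets, len(tiles), anchor=anchor)
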