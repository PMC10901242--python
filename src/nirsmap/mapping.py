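"""Spatial lesion-probability map construction.

Stages: fit a projective transform from control points (physical mm to
reference-image pixels), linearly interpolate scattered per-point lesion
probabilities onto a uniform grid, mask the grid to a concave boundary
around the pooled sampled points (alpha shape), and smooth with a
zero-phase 2-D lowpass (cutoff 0.1 pi rad/sample) using normalized
masked convolution so undefined cells never bleed into defined ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.signal import butter, filtfilt
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage.transform import ProjectiveTransform

from .types import BinaryMap, Homography, ProbabilityMap, ValidationError

CUTOFF_2D = 0.1
FILTER_ORDER_2D = 4
DEFAULT_SPACING_MM = 0.5


class FitError(ValueError):
    pass


@dataclass
class ControlPointSet:
    """Paired physical (x, y) mm and image (u, v) pixel locations."""

    physical: np.ndarray  # (n, 2) mm
    pixels: np.ndarray  # (n, 2) 0-based (u = column, v = row)

    def __post_init__(self) -> None:
        self.physical = np.asarray(self.physical, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.physical.shape != self.pixels.shape or self.physical.ndim != 2:
            raise ValidationError("physical and pixel arrays must both be (n, 2)")
        if len(self.physical) < 4:
            raise ValidationError("need at least 4 control points")
        if len(self.physical) == 4 and _any_three_collinear(self.physical):
            raise ValidationError("3 of 4 physical control points are collinear")


def _any_three_collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    from itertools import combinations

    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area = abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
        scale = max(np.abs(np.r_[b - a, c - a]).max(), 1.0)
        if area <= tol * scale**2:
            return True
    return False


def fit_projective(cps: ControlPointSet) -> Homography:
    """Least-squares homography physical -> pixel (normalized DLT)."""
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(cps.physical, cps.pixels)
        ok = bool(tf)
        H = tf.params if ok else np.full((3, 3), np.nan)
    else:
        tf = ProjectiveTransform()
        ok = tf.estimate(cps.physical, cps.pixels)
        H = tf.params
    if not ok or not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12:
        raise FitError("degenerate control-point configuration")
    return Homography(H)


def _grid_for_points(
    points: np.ndarray, spacing: float, margin: float
) -> tuple[tuple[float, float], np.ndarray, np.ndarray]:
    x0 = np.floor((points[:, 0].min() - margin) / spacing) * spacing
    y0 = np.floor((points[:, 1].min() - margin) / spacing) * spacing
    nx = int(np.ceil((points[:, 0].max() + margin - x0) / spacing)) + 1
    ny = int(np.ceil((points[:, 1].max() + margin - y0) / spacing)) + 1
    xs = x0 + spacing * np.arange(nx)
    ys = y0 + spacing * np.arange(ny)
    return (float(x0), float(y0)), xs, ys


def interpolate_scattered(
    points: np.ndarray,
    values: np.ndarray,
    spacing: float = DEFAULT_SPACING_MM,
    margin: float = 0.0,
    extent_points: np.ndarray | None = None,
) -> ProbabilityMap:
    """Triangulation-based linear interpolation onto a uniform grid.

    Cells outside the convex hull of ``points`` are undefined.  The grid
    extent derives from ``extent_points`` when given (e.g. a pooled
    point cloud shared by paired maps), else from ``points``.
    """
    points = np.asarray(points, dtype=float)
    values = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    if len(points) < 3:
        raise ValidationError("need >= 3 points")
    try:
        interp = LinearNDInterpolator(points, values)
    except QhullError as e:
        raise ValidationError(f"degenerate (collinear) point set: {e}") from e
    ext = points if extent_points is None else np.asarray(extent_points, float)
    origin, xs, ys = _grid_for_points(ext, spacing, margin)
    gx, gy = np.meshgrid(xs, ys)
    vals = interp(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    mask = np.isfinite(vals)
    return ProbabilityMap(origin=origin, spacing=spacing, values=vals, mask=mask)


def _circumradii(points: np.ndarray, tri: Delaunay) -> np.ndarray:
    a = points[tri.simplices[:, 0]]
    b = points[tri.simplices[:, 1]]
    c = points[tri.simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    )
    with np.errstate(divide="ignore"):
        r = la * lb * lc / (2.0 * np.maximum(area2, 1e-300))
    return r


def _connected(simplices: np.ndarray, keep: np.ndarray) -> bool:
    kept = np.flatnonzero(keep)
    if len(kept) == 0:
        return False
    # union-find over triangles sharing a vertex
    parent = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    vert_owner: dict[int, int] = {}
    for t in kept:
        for v in simplices[t]:
            if v in vert_owner:
                union(int(t), vert_owner[v])
            else:
                vert_owner[v] = int(t)
    roots = {find(int(t)) for t in kept}
    return len(roots) == 1


def _auto_alpha(points: np.ndarray, tri: Delaunay, radii: np.ndarray) -> float:
    """Smallest circumradius cutoff giving one connected region covering
    every input point."""
    n_points = len(points)
    candidates = np.unique(radii)

    def ok(alpha: float) -> bool:
        keep = radii <= alpha
        if not keep.any():
            return False
        verts = np.unique(tri.simplices[keep])
        return len(verts) == n_points and _connected(tri.simplices, keep)

    lo, hi = 0, len(candidates) - 1
    if not ok(candidates[hi]):
        raise ValidationError("no alpha yields a valid concave boundary")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def concave_mask(
    points: np.ndarray,
    grid_map: ProbabilityMap,
    alpha: float | None = None,
) -> np.ndarray:
    """Boolean mask of grid cells inside the alpha shape of ``points``.

    ``alpha`` is a circumradius cutoff in mm: Delaunay triangles with a
    larger circumradius are carved away, generalizing the convex hull
    (``alpha = inf`` recovers it).  When None, the smallest alpha giving
    a single connected region containing all points is used.  Every
    input point maps to a masked-in cell region by construction.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValidationError("need >= 4 points for a concave boundary")
    try:
        tri = Delaunay(points)
    except QhullError as e:
        raise ValidationError(f"degenerate point set: {e}") from e
    radii = _circumradii(points, tri)
    if alpha is None:
        alpha = _auto_alpha(points, tri, radii)
    keep = radii <= alpha
    if not keep.any():
        raise ValidationError(
            f"alpha = {alpha} mm removes every triangle; use a larger alpha"
        )
    verts = np.unique(tri.simplices[keep])
    if len(verts) < len(points):
        raise ValidationError(
            f"alpha = {alpha} mm excludes input points; use a larger alpha"
        )
    xs, ys = grid_map.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    simplex = tri.find_simplex(np.column_stack([gx.ravel(), gy.ravel()]))
    inside = simplex >= 0
    inside[inside] = keep[simplex[inside]]
    return inside.reshape(gx.shape)


def apply_mask(pmap: ProbabilityMap, mask: np.ndarray) -> ProbabilityMap:
    """Restrict a map to ``mask`` (intersected with already-defined cells)."""
    new_mask = pmap.mask & mask
    vals = np.where(new_mask, pmap.values, np.nan)
    return ProbabilityMap(pmap.origin, pmap.spacing, vals, new_mask)


def lowpass_2d(pmap: ProbabilityMap, cutoff: float = CUTOFF_2D) -> ProbabilityMap:
    """Separable zero-phase 2-D lowpass over the masked region.

    Normalized masked convolution: the map (zero-filled outside the
    mask) and the mask itself are filtered identically and divided, so
    undefined cells carry no weight.  The mask is unchanged and output
    values are clipped to [0, 1].
    """
    if not pmap.mask.any():
        raise ValidationError("empty mask")
    b, a = butter(FILTER_ORDER_2D, cutoff)
    maskf = pmap.mask.astype(float)
    vals = np.where(pmap.mask, pmap.values, 0.0)

    def filt2(z: np.ndarray) -> np.ndarray:
        for axis in (0, 1):
            n = z.shape[axis]
            padlen = min(3 * max(len(a), len(b)), n - 1)
            z = filtfilt(b, a, z, axis=axis, padlen=padlen)
        return z

    num = filt2(vals)
    den = filt2(maskf)
    out = np.full_like(vals, np.nan)
    good = pmap.mask & (den > 1e-9)
    out[good] = np.clip(num[good] / den[good], 0.0, 1.0)
    new_mask = pmap.mask & good
    out[~new_mask] = np.nan
    return ProbabilityMap(pmap.origin, pmap.spacing, out, new_mask)


def threshold_map(pmap: ProbabilityMap, p: float) -> BinaryMap:
    """Binary lesion prediction: defined cells with value >= p."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    pred = pmap.mask & (np.nan_to_num(pmap.values, nan=-1.0) >= p)
    return BinaryMap(pmap.origin, pmap.spacing, pred, pmap.mask.copy())


def build_probability_map(
    points: np.ndarray,
    values: np.ndarray,
    boundary_points: np.ndarray | None = None,
    spacing: float = DEFAULT_SPACING_MM,
    alpha: float | None = None,
    cutoff: float = CUTOFF_2D,
) -> ProbabilityMap:
    """Full map pipeline: interpolate, concave-mask, lowpass.

    ``boundary_points`` (default: the data points) defines the common
    concave boundary — pass the pooled PBS + blood point cloud so paired
    maps share one mask.
    """
    bpts = points if boundary_points is None else np.asarray(boundary_points, float)
    pmap = interpolate_scattered(points, values, spacing=spacing, extent_points=bpts)
    mask = concave_mask(bpts, pmap, alpha=alpha)
    pmap = apply_mask(pmap, mask)
    return lowpass_2d(pmap, cutoff=cutoff)


def convex_hull_area(points: np.ndarray) -> float:
    """Area (mm^2) of the convex hull; oracle helper for mask sanity."""
    return float(ConvexHull(np.asarray(points, dtype=float)).volume)
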