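"""Scriptable equivalents of the interactive segmentation tools.

Each tool writes only to its declared target layer (``selection`` by
default, optionally ``mask``); the image layer is never mutated.  Painting
tools mutate the dataset in place (appending a log entry) and return it;
query tools (:func:`magic_wand`, :func:`region_grow`) return a binary
region for the caller to combine.

Coordinates are ``(z, y, x)`` voxel indices throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import graph as skgraph

from .core import LayeredDataset, register_op

__all__ = [
    "ToolStroke",
    "ClickSequence",
    "paint_primitive",
    "brush",
    "brush_superpixels",
    "magic_wand",
    "region_grow",
    "membrane_track_2d",
    "line_track_3d",
    "shape_interpolate",
    "line_interpolate",
    "threshold_bw",
]


@dataclass(frozen=True)
class ToolStroke:
    """Polyline brush stroke on one slice.

    ``points`` are ``(y, x)`` voxel coordinates in stroke order, ``slice_index``
    the Z slice, ``radius`` the brush radius in voxels (0 = single-voxel pen).
    """

    points: tuple[tuple[int, int], ...]
    slice_index: int
    radius: int = 1
    target_layer: str = "selection"

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("stroke radius must be >= 0")
        if not self.points:
            raise ValueError("stroke needs at least one point")
        if self.target_layer not in ("selection", "mask"):
            raise ValueError("target layer must be 'selection' or 'mask'")


@dataclass(frozen=True)
class ClickSequence:
    """Ordered anchor clicks for the membrane / line trackers.

    2-D tracking: ``points`` are ``(y, x)`` on slice ``slice_index``.
    3-D tracking: ``points`` are ``(z, y, x)``, ordered in Z.
    ``corridor`` is the half-width (voxels) of the search band around the
    straight segment between consecutive clicks.
    """

    points: tuple[tuple, ...]
    slice_index: int | None = None
    corridor: int = 20

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("need at least 2 anchor points")
        for a, b in zip(self.points, self.points[1:]):
            if tuple(a) == tuple(b):
                raise ValueError("consecutive anchor points must be distinct")


# ---------------------------------------------------------------------------
# painting primitives


def _check_bounds(ds: LayeredDataset, zyx: Sequence[float]) -> None:
    for v, n in zip(zyx, ds.shape):
        if not 0 <= int(v) < n:
            raise IndexError(f"point {tuple(zyx)} outside volume {ds.shape}")


def paint_primitive(ds: LayeredDataset, kind: str, center: Sequence[float],
                    radius: float, target_layer: str = "selection") -> LayeredDataset:
    """Paint a filled 2-D disk (``spot``) or physical 3-D sphere (``ball3d``).

    ``ball3d`` corrects for anisotropy: the painted voxel footprint is the
    ellipsoid whose *physical* shape is a sphere of the given physical
    radius (e.g. radius 10 nm at voxel size (5, 5, 10) nm paints semi-axes
    (2, 2, 1) voxels).  ``spot`` uses a voxel-radius disk on one slice.
    The footprint is OR-ed into the target layer.
    """
    _check_bounds(ds, center)
    layer = ds.get_layer(target_layer)
    z, y, x = (float(c) for c in center)
    if kind == "spot":
        rr, cc = skdraw.disk((y, x), max(radius, 0.5), shape=ds.shape[1:])
        layer[int(round(z)), rr, cc] = True
    elif kind == "ball3d":
        dx, dy, dz = ds.geometry.voxel_size
        rz, ry, rx = (max(radius / d, 0.5) for d in (dz, dy, dx))
        zz, yy, xx = np.ogrid[tuple(slice(0, n) for n in ds.shape)]
        m = ((zz - z) / rz) ** 2 + ((yy - y) / ry) ** 2 + ((xx - x) / rx) ** 2 <= 1.0
        layer |= m
    else:
        raise ValueError("kind must be 'spot' or 'ball3d'")
    ds.log.append("paint_primitive", {"kind": kind, "center": list(center),
                                      "radius": radius, "target_layer": target_layer})
    return ds


def _stroke_footprint(stroke: ToolStroke, plane_shape: tuple[int, int]) -> np.ndarray:
    path = np.zeros(plane_shape, dtype=bool)
    pts = [tuple(int(round(v)) for v in p) for p in stroke.points]
    if len(pts) == 1:
        path[pts[0]] = True
    for a, b in zip(pts, pts[1:]):
        rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
        ok = (rr >= 0) & (rr < plane_shape[0]) & (cc >= 0) & (cc < plane_shape[1])
        path[rr[ok], cc[ok]] = True
    if stroke.radius > 0:
        path = ndi.distance_transform_edt(~path) <= stroke.radius
    return path


def brush(ds: LayeredDataset, stroke: ToolStroke, mode: str = "paint") -> LayeredDataset:
    """Paint (or erase) the union of disks along a polyline stroke.

    The footprint is gap-free for any inter-point spacing (the polyline is
    rasterized 8-connected, then dilated to the brush radius) and confined
    to the stroke's slice.
    """
    for p in stroke.points:
        _check_bounds(ds, (stroke.slice_index, *p))
    layer = ds.get_layer(stroke.target_layer)
    foot = _stroke_footprint(stroke, ds.shape[1:])
    if mode == "paint":
        layer[stroke.slice_index] |= foot
    elif mode == "erase":
        layer[stroke.slice_index] &= ~foot
    else:
        raise ValueError("mode must be 'paint' or 'erase'")
    ds.log.append("brush", {"points": [list(p) for p in stroke.points],
                            "slice_index": stroke.slice_index, "radius": stroke.radius,
                            "target_layer": stroke.target_layer, "mode": mode})
    return ds


def brush_superpixels(ds: LayeredDataset, stroke: ToolStroke, partition) -> LayeredDataset:
    """Select whole superpixels touched by a brush stroke.

    Selects the union of all superpixels whose footprint intersects the
    plain-brush footprint — always a superset of :func:`brush` output.
    ``partition`` is a :class:`~volseg.segauto.SupervoxelPartition` (2-D
    for the slice, or 3-D covering it).
    """
    if partition is None:
        raise ValueError("no superpixel partition given; compute SLIC first "
                         "(volseg.segauto.slic) and pass the partition")
    labels = partition.labels
    z = stroke.slice_index
    plane_labels = labels[z] if labels.ndim == 3 else labels
    if plane_labels.shape != ds.shape[1:]:
        raise ValueError("partition shape does not match the dataset slice")
    foot = _stroke_footprint(stroke, ds.shape[1:])
    touched = np.unique(plane_labels[foot])
    region = np.isin(plane_labels, touched)
    layer = ds.get_layer(stroke.target_layer)
    layer[z] |= region | foot
    ds.log.append("brush_superpixels", {"points": [list(p) for p in stroke.points],
                                        "slice_index": z, "radius": stroke.radius,
                                        "n_superpixels": int(touched.size)})
    return ds


# ---------------------------------------------------------------------------
# region selection


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    # 4/8 in 2-D, 6/26 in 3-D
    order = {4: 1, 8: 2, 6: 1, 26: 3, 18: 2}
    if connectivity not in order:
        raise ValueError(f"connectivity must be one of 4/8 (2-D) or 6/18/26 (3-D), got {connectivity}")
    return ndi.generate_binary_structure(ndim, order[connectivity])


def magic_wand(ds: LayeredDataset, seed: Sequence[int], tolerance=(10, 10),
               connectivity: int | None = None, scope: str = "3d") -> np.ndarray:
    """Connected intensity-window region around a seed voxel.

    Selects the connected component containing ``seed`` of voxels whose
    intensity lies in ``[I(seed) - tolerance[0], I(seed) + tolerance[1]]``
    under the given connectivity (default 8 in 2-D, 26 in 3-D).
    Returns a ``(z, y, x)`` boolean volume (single-slice extent for
    ``scope='2d'`` is returned full-shape with other slices empty).
    """
    _check_bounds(ds, seed)
    z, y, x = (int(v) for v in seed)
    img = ds.grayscale()
    i0 = img[z, y, x]
    lo, hi = (float(tolerance[0]), float(tolerance[1])) if np.iterable(tolerance) \
        else (float(tolerance), float(tolerance))
    window = (img >= i0 - lo) & (img <= i0 + hi)
    out = np.zeros(ds.shape, dtype=bool)
    if scope == "2d":
        conn = connectivity or 8
        lab, _ = ndi.label(window[z], structure=_structure(2, conn))
        out[z] = lab == lab[y, x]
    elif scope == "3d":
        conn = connectivity or 26
        lab, _ = ndi.label(window, structure=_structure(3, conn))
        out = lab == lab[z, y, x]
    else:
        raise ValueError("scope must be '2d' or '3d'")
    return out


def region_grow(ds: LayeredDataset, seed: Sequence[int], kappa: float = 10.0,
                max_iter: int = 10_000, connectivity: int = 26,
                scope: str = "3d") -> np.ndarray:
    """Iterative region growing against the evolving region mean.

    Wave-by-wave breadth-first growth: each iteration admits every
    frontier voxel whose intensity is within ``kappa`` of the current
    region mean, then updates the mean.  Whole waves are admitted at once,
    so the result is deterministic and independent of voxel ordering.
    """
    _check_bounds(ds, seed)
    img = ds.grayscale()
    z, y, x = (int(v) for v in seed)
    if scope == "2d":
        plane = img[z]
        region2d = _region_grow_nd(plane, (y, x), kappa, max_iter, _structure(2, min(connectivity, 8)))
        out = np.zeros(ds.shape, dtype=bool)
        out[z] = region2d
        return out
    return _region_grow_nd(img, (z, y, x), kappa, max_iter, _structure(3, connectivity))


def _region_grow_nd(img, seed, kappa, max_iter, structure) -> np.ndarray:
    region = np.zeros(img.shape, dtype=bool)
    region[tuple(seed)] = True
    total = float(img[tuple(seed)])
    count = 1
    for _ in range(max_iter):
        frontier = ndi.binary_dilation(region, structure=structure) & ~region
        if not frontier.any():
            break
        mean = total / count
        admit = frontier & (np.abs(img - mean) <= kappa)
        if not admit.any():
            break
        region |= admit
        total += float(img[admit].sum())
        count += int(admit.sum())
    return region


# ---------------------------------------------------------------------------
# trackers


def membrane_track_2d(ds: LayeredDataset, clicks: ClickSequence,
                      smoothing: float = 1.0) -> np.ndarray:
    """Trace a membrane between anchor clicks by minimal-cost pathfinding.

    The voxel cost decreases with membrane evidence — by default the
    smoothed intensity itself (dark ridges are cheap, EM polarity) — plus
    a tiny pull toward the straight chord so ties resolve to the direct
    discrete segment.  Each consecutive click pair is routed independently
    inside a corridor of ``clicks.corridor`` voxels around its chord; the
    paths are concatenated into a width-1 boolean volume.
    """
    if clicks.slice_index is None:
        raise ValueError("2-D tracking requires clicks.slice_index")
    z = clicks.slice_index
    img = ds.grayscale()[z]
    cost = ndi.gaussian_filter(img, smoothing)
    cost = cost - cost.min() + 1.0  # strictly positive for the router
    out = np.zeros(ds.shape, dtype=bool)
    for p0, p1 in zip(clicks.points, clicks.points[1:]):
        p0 = tuple(int(v) for v in p0)
        p1 = tuple(int(v) for v in p1)
        seg_cost = _corridor_cost(cost, p0, p1, clicks.corridor)
        try:
            path, _ = skgraph.route_through_array(seg_cost, p0, p1,
                                                  fully_connected=True, geometric=True)
        except ValueError as e:
            raise ValueError(f"no path within corridor for segment {p0}->{p1}") from e
        for (yy, xx) in path:
            out[z, yy, xx] = True
    return out


def _corridor_cost(cost: np.ndarray, p0, p1, corridor: int) -> np.ndarray:
    yy, xx = np.mgrid[0:cost.shape[0], 0:cost.shape[1]]
    a = np.array(p0, dtype=float)
    b = np.array(p1, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((yy - a[0]) * ab[0] + (xx - a[1]) * ab[1]) / denom, 0, 1)
    dy = yy - (a[0] + t * ab[0])
    dx = xx - (a[1] + t * ab[1])
    dist = np.hypot(dy, dx)
    out = cost + 1e-4 * dist  # deterministic tie-break toward the chord
    out[dist > corridor] = np.inf
    return out


def line_track_3d(ds: LayeredDataset, clicks: ClickSequence,
                  radius: float = 0.0) -> np.ndarray:
    """Piecewise-linear centreline through 3-D anchors (microtubule style).

    Anchors are interpolated linearly in *physical* coordinates and
    rasterized one node per intersected Z slice, so the path honours
    anisotropic voxel size.  ``radius > 0`` dilates the centreline to a
    physical tube radius.
    """
    pts = [tuple(float(v) for v in p) for p in clicks.points]
    for a, b in zip(pts, pts[1:]):
        if int(round(a[0])) == int(round(b[0])):
            raise ValueError("two clicks on the same slice within one segment")
    if any(b[0] < a[0] for a, b in zip(pts, pts[1:])):
        raise ValueError("clicks must be ordered by increasing Z")
    dz, dy, dx = ds.geometry.spacing_zyx
    out = np.zeros(ds.shape, dtype=bool)
    for a, b in zip(pts, pts[1:]):
        z0, z1 = int(round(a[0])), int(round(b[0]))
        pa = np.array([a[0] * dz, a[1] * dy, a[2] * dx])
        pb = np.array([b[0] * dz, b[1] * dy, b[2] * dx])
        for z in range(z0, z1 + 1):
            t = (z * dz - pa[0]) / (pb[0] - pa[0])
            phys = pa + np.clip(t, 0, 1) * (pb - pa)
            y = int(round(phys[1] / dy))
            x = int(round(phys[2] / dx))
            if 0 <= z < ds.shape[0] and 0 <= y < ds.shape[1] and 0 <= x < ds.shape[2]:
                out[z, y, x] = True
    if radius > 0:
        dist = ndi.distance_transform_edt(~out, sampling=(dz, dy, dx))
        out = dist <= radius
    return out


# ---------------------------------------------------------------------------
# slice interpolation


def _sdf(fg: np.ndarray) -> np.ndarray:
    # positive outside, negative inside; zero level at the object boundary
    return ndi.distance_transform_edt(~fg) - ndi.distance_transform_edt(fg)


def shape_interpolate(layer: np.ndarray, slice_a: int, slice_b: int,
                      overwrite: bool = False) -> np.ndarray:
    """Morphological interpolation of filled shapes between two key slices.

    Intermediate slice at fraction ``t`` is the zero-sublevel set of the
    blended signed distance fields ``(1 - t) * SDF_a + t * SDF_b``, which
    reproduces the key slices exactly at t = 0, 1 and morphs smoothly in
    between.  Multiple objects per key slice are matched by centroid
    proximity and blended pairwise; unmatched objects are copied unchanged
    with a warning.  Returns a copy of ``layer`` with the intermediate
    slices filled.
    """
    layer = np.asarray(layer).astype(bool)
    if slice_a > slice_b:
        slice_a, slice_b = slice_b, slice_a
    fa, fb = layer[slice_a], layer[slice_b]
    if not fa.any() or not fb.any():
        raise ValueError("both key slices must contain a foreground object")
    inter = range(slice_a + 1, slice_b)
    if not overwrite and any(layer[k].any() for k in inter):
        raise ValueError("intermediate slices are not empty (pass overwrite=True)")

    pairs, lone_a, lone_b = _match_objects(fa, fb)
    out = layer.copy()
    if len(inter) == 0:
        return out
    blends = [( _sdf(ma), _sdf(mb)) for ma, mb in pairs]
    for k in inter:
        # integer weights (b-k, k-a) instead of (1-t, t): scaling the SDF
        # blend by (b-a) leaves the zero level set unchanged and makes the
        # a->b and b->a directions bit-identical
        wa, wb = slice_b - k, k - slice_a
        plane = np.zeros_like(fa)
        for sa, sb in blends:
            plane |= (wa * sa + wb * sb) <= 0
        for m in lone_a + lone_b:
            plane |= m
        out[k] = plane
    if lone_a or lone_b:
        warnings.warn(f"{len(lone_a) + len(lone_b)} unmatched object(s) copied "
                      "unchanged through the interpolation range", stacklevel=2)
    return out


def _match_objects(fa: np.ndarray, fb: np.ndarray):
    la, na = ndi.label(fa)
    lb, nb = ndi.label(fb)
    ca = ndi.center_of_mass(fa, la, range(1, na + 1))
    cb = ndi.center_of_mass(fb, lb, range(1, nb + 1))
    cand = sorted(
        ((np.hypot(*(np.array(ca[i]) - np.array(cb[j]))), i, j)
         for i in range(na) for j in range(nb)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a, used_b, pairs = set(), set(), []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((la == i + 1, lb == j + 1))
    lone_a = [la == i + 1 for i in range(na) if i not in used_a]
    lone_b = [lb == j + 1 for j in range(nb) if j not in used_b]
    return pairs, lone_a, lone_b


def _trace_curve(plane: np.ndarray) -> np.ndarray:
    """Order the voxels of a simple open 8-connected 1-px curve."""
    pts = set(map(tuple, np.argwhere(plane)))
    if not pts:
        raise ValueError("key slice contains no curve")

    def neighbors(p):
        return [q for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy or dx) and (q := (p[0] + dy, p[1] + dx)) in pts]

    degree = {p: len(neighbors(p)) for p in pts}
    if any(d > 2 for d in degree.values()):
        raise ValueError("branching curves are not supported (only simple open curves)")
    ends = sorted(p for p, d in degree.items() if d <= 1)
    if len(ends) != 2:
        raise ValueError("curve must be open (exactly two endpoints)")
    order = [ends[0]]
    prev = None
    while True:
        nxt = [q for q in neighbors(order[-1]) if q != prev]
        if not nxt:
            break
        prev = order[-1]
        order.append(nxt[0])
        if order[-1] == ends[1] and len(order) == len(pts):
            break
    if len(order) != len(pts):
        raise ValueError("curve voxels do not form a single connected path")
    return np.array(order, dtype=float)


def line_interpolate(layer: np.ndarray, slice_a: int, slice_b: int,
                     overwrite: bool = False) -> np.ndarray:
    """Interpolate open 1-px contours between two key slices.

    Both curves are resampled to equal arc-length point counts, endpoints
    matched by proximity (the second curve is reversed if that brings its
    endpoints closer), blended point-wise linearly, and re-rasterized per
    intermediate slice.
    """
    layer = np.asarray(layer).astype(bool)
    if slice_a > slice_b:
        slice_a, slice_b = slice_b, slice_a
    ca = _trace_curve(layer[slice_a])
    cb = _trace_curve(layer[slice_b])
    if (np.linalg.norm(ca[0] - cb[0]) + np.linalg.norm(ca[-1] - cb[-1])
            > np.linalg.norm(ca[0] - cb[-1]) + np.linalg.norm(ca[-1] - cb[0])):
        cb = cb[::-1]
    n = max(len(ca), len(cb), 2)
    ra, rb = _resample(ca, n), _resample(cb, n)
    out = layer.copy()
    for k in range(slice_a + 1, slice_b):
        if not overwrite and out[k].any():
            raise ValueError("intermediate slices are not empty (pass overwrite=True)")
        t = (k - slice_a) / (slice_b - slice_a)
        pts = (1 - t) * ra + t * rb
        plane = np.zeros_like(out[k])
        ip = np.rint(pts).astype(int)
        ip[:, 0] = np.clip(ip[:, 0], 0, plane.shape[0] - 1)
        ip[:, 1] = np.clip(ip[:, 1], 0, plane.shape[1] - 1)
        for p, q in zip(ip, ip[1:]):
            rr, cc = skdraw.line(p[0], p[1], q[0], q[1])
            plane[rr, cc] = True
        out[k] = plane
    return out


def _resample(curve: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(curve[:1], n, axis=0)
    ts = np.linspace(0, s[-1], n)
    return np.stack([np.interp(ts, s, curve[:, d]) for d in range(curve.shape[1])], axis=1)


# ---------------------------------------------------------------------------
# thresholding


@register_op("threshold_bw")
def threshold_bw(ds: LayeredDataset, window: Sequence[float], scope: str = "whole",
                 per: str = "volume") -> LayeredDataset:
    """Black-and-white intensity thresholding into the selection layer.

    Selects voxels with ``low <= I <= high`` (inclusive both ends).
    ``scope='masked'`` intersects the result with the mask layer, giving
    local thresholding of a pre-masked area.  ``per`` controls whether the
    window is applied volume-wide or slice-by-slice (identical output for
    a fixed window; retained for pipeline parity).
    """
    low, high = float(window[0]), float(window[1])
    if low > high:
        raise ValueError(f"threshold window low {low} > high {high}")
    if scope not in ("whole", "masked"):
        raise ValueError("scope must be 'whole' or 'masked'")
    img = ds.grayscale()
    if per == "slice":
        sel = np.stack([(img[z] >= low) & (img[z] <= high) for z in range(img.shape[0])])
    else:
        sel = (img >= low) & (img <= high)
    if scope == "masked":
        if not ds.has_mask or not ds.mask.any():
            raise ValueError("masked thresholding requires a nonempty mask layer")
        sel &= ds.mask
    new = ds.copy()
    new.selection = sel
    new.log.append("threshold_bw", {"window": [low, high], "scope": scope, "per": per})
    return new
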