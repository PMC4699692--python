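"""Object quantification and property-based filtering.

Connected-component labelling in 2-D (per slice) or 3-D with per-object
shape and intensity properties in physical units (anisotropy honoured),
range-predicate filtering used as a segmentation-polishing stage,
per-material model smoothing, and manual geometric measurements
(distance, angle, caliper, circle-fit radius) with intensity profiles.

Estimator choices: eccentricity and orientation come from second-order
moments (the ellipse/ellipsoid-equivalent); 2-D perimeter uses the
Crofton edge-crossing estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure

from .core import LayeredDataset, MODEL_DTYPE
from .geometry import VolumeGeometry

__all__ = [
    "ObjectTable",
    "Measurement",
    "label_objects",
    "filter_objects",
    "smooth_model",
    "measure",
    "export_table",
]


PHYSICAL_COLUMNS = {
    "volume": "{u}^3", "area": "{u}^2", "perimeter": "{u}",
    "centroid_x": "{u}", "centroid_y": "{u}", "centroid_z": "{u}",
}


@dataclass
class ObjectTable:
    """Per-object property table for labelled components.

    ``df`` holds one row per connected component with both voxel-unit and
    physical-unit columns; ``units`` names the physical length unit;
    ``mode`` records the labelling dimensionality (``'3d'`` or
    ``'2d-per-slice'``).
    """

    df: pd.DataFrame
    units: str
    mode: str

    def __len__(self) -> int:
        return len(self.df)

    def column_units(self) -> dict[str, str]:
        u = self.units
        return {c: t.format(u=u) for c, t in PHYSICAL_COLUMNS.items() if c in self.df.columns}


def label_objects(binary: np.ndarray, dims: str = "3d", connectivity: int | None = None,
                  intensity: np.ndarray | LayeredDataset | None = None,
                  geometry: VolumeGeometry | None = None
                  ) -> tuple[np.ndarray, ObjectTable]:
    """Label connected components and tabulate their properties.

    ``dims='3d'`` labels the volume (default 26-connectivity);
    ``dims='2d-per-slice'`` labels each slice independently (default
    8-connectivity) and adds a ``slice`` column.  Physical sizes use the
    geometry's voxel dimensions.  Empty input gives an empty table.
    """
    if isinstance(intensity, LayeredDataset):
        geometry = geometry or intensity.geometry
        intensity = intensity.grayscale()
    geometry = geometry or VolumeGeometry()
    binary = np.asarray(binary).astype(bool)
    dz, dy, dx = geometry.spacing_zyx
    x0, y0, z0 = geometry.bbox_min

    rows: list[dict] = []
    if dims == "3d":
        struct = ndi.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}.get(connectivity or 26))
        labels, n = ndi.label(binary, structure=struct)
        for p in skmeasure.regionprops(labels, intensity_image=intensity):
            cz, cy, cx = p.centroid
            row = {
                "id": p.label, "slice": -1, "n_voxels": int(p.num_pixels),
                "volume": p.num_pixels * geometry.voxel_volume,
                "eccentricity": _ecc3d(p), "perimeter": np.nan, "orientation": np.nan,
                "centroid_x": x0 + (cx + 0.5) * dx, "centroid_y": y0 + (cy + 0.5) * dy,
                "centroid_z": z0 + (cz + 0.5) * dz,
            }
            rows.append(_with_intensity(row, p, intensity is not None))
        table_labels = labels
    elif dims == "2d-per-slice":
        struct2 = ndi.generate_binary_structure(2, {4: 1, 8: 2}.get(connectivity or 8))
        table_labels = np.zeros(binary.shape, dtype=np.int32)
        offset = 0
        for z in range(binary.shape[0]):
            labels, n = ndi.label(binary[z], structure=struct2)
            inten = intensity[z] if intensity is not None else None
            for p in skmeasure.regionprops(labels, intensity_image=inten):
                cy, cx = p.centroid
                row = {
                    "id": p.label + offset, "slice": z, "n_voxels": int(p.num_pixels),
                    "area": p.num_pixels * dx * dy,
                    "eccentricity": float(p.eccentricity),
                    "perimeter": float(p.perimeter_crofton) * dx,
                    "orientation": float(np.degrees(p.orientation)),
                    "centroid_x": x0 + (cx + 0.5) * dx, "centroid_y": y0 + (cy + 0.5) * dy,
                    "centroid_z": z0 + (z + 0.5) * dz,
                }
                rows.append(_with_intensity(row, p, inten is not None))
            table_labels[z][labels > 0] = labels[labels > 0] + offset
            offset += n
    else:
        raise ValueError("dims must be '3d' or '2d-per-slice'")

    columns = ["id", "slice", "n_voxels",
               "volume" if dims == "3d" else "area",
               "eccentricity", "perimeter", "orientation",
               "centroid_x", "centroid_y", "centroid_z",
               "intensity_min", "intensity_max", "intensity_mean"]
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return table_labels, ObjectTable(df, geometry.units, dims)


def _ecc3d(p) -> float:
    # ellipsoid-equivalent eccentricity from the inertia tensor:
    # sqrt(1 - (minor/major)^2) of the equivalent semi-axes
    ev = np.sort(np.clip(p.inertia_tensor_eigvals, 0, None))
    if ev[-1] <= 0:
        return 0.0
    # eigenvalues ~ sum of squares of the two other semi-axes; recover axes
    s = ev.sum() / 2.0
    axes2 = np.clip([s - e for e in ev], 0, None)  # descending semi-axis^2
    if axes2[0] <= 0:
        return 0.0
    return float(np.sqrt(1.0 - min(axes2[-1] / axes2[0], 1.0)))


def _with_intensity(row: dict, p, has_intensity: bool) -> dict:
    if has_intensity:
        row.update(intensity_min=float(p.intensity_min),
                   intensity_max=float(p.intensity_max),
                   intensity_mean=float(p.intensity_mean))
    else:
        row.update(intensity_min=np.nan, intensity_max=np.nan, intensity_mean=np.nan)
    return row


def filter_objects(labels: np.ndarray, table: ObjectTable,
                   predicate: dict[str, tuple[float | None, float | None]],
                   log=None) -> tuple[np.ndarray, ObjectTable]:
    """Keep only objects whose properties fall inside every given range.

    ``predicate`` maps column names to ``(lo, hi)`` bounds (either bound
    may be None).  Failing objects are removed from both the table and
    the label volume.  Idempotent; an all-pass predicate is the identity.
    """
    df = table.df
    keep = pd.Series(True, index=df.index)
    for col, (lo, hi) in predicate.items():
        if col not in df.columns:
            raise KeyError(f"unknown property {col!r}; available: {list(df.columns)}")
        if lo is not None:
            keep &= df[col] >= lo
        if hi is not None:
            keep &= df[col] <= hi
    surviving = set(df.loc[keep, "id"].astype(int))
    removed = int((~keep).sum())
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=labels.dtype)
    for i in surviving:
        lut[i] = i
    out_labels = lut[labels]
    if log is not None:
        log.append("filter_objects", {"predicate": {k: [v[0], v[1]] for k, v in predicate.items()},
                                      "removed": removed})
    return out_labels, ObjectTable(df.loc[keep].reset_index(drop=True), table.units, table.mode)


def smooth_model(model: np.ndarray, radius: int = 1, dims: str = "3d") -> np.ndarray:
    """Per-material binary opening (erosion then dilation) of a label volume.

    Materials are processed independently; where the smoothed footprints
    of two materials would overlap, the voxel keeps its original label, so
    adjacent materials never bleed into each other.
    """
    from .filters import morphology as _morph
    model = np.asarray(model)
    out = np.zeros_like(model)
    claims = np.zeros(model.shape, dtype=np.uint8)
    smoothed = {}
    for m in np.unique(model):
        if m == 0:
            continue
        sm = _morph(model == m, "opening", radius=radius, dims=dims)
        smoothed[int(m)] = sm
        claims += sm.astype(np.uint8)
    for m, sm in smoothed.items():
        sole = sm & (claims == 1)
        out[sole] = m
        both = sm & (claims > 1) & (model == m)  # conflict: original label wins
        out[both] = m
    return out.astype(model.dtype)


# ---------------------------------------------------------------------------
# manual measurements


@dataclass
class Measurement:
    """One manual geometric measurement with its intensity profile.

    ``anchors`` are physical ``(x, y, z)`` points; ``profile`` is a
    ``(position, value)`` array sampled along the measured path at a
    spacing no coarser than the smallest voxel dimension.
    """

    kind: str
    anchors: tuple
    value: float
    units: str
    profile: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def measure(ds: LayeredDataset, kind: str, anchors: Sequence[Sequence[float]],
            object_mask: np.ndarray | None = None,
            direction: Sequence[float] | None = None) -> Measurement:
    """Manual measurement between physical anchor points.

    * ``distance`` — Euclidean distance between 2 points.
    * ``angle`` — angle at the middle of 3 points, in [0°, 180°].
    * ``caliper`` — maximal extent of ``object_mask`` projected on the
      direction of the 2 anchors (or explicit ``direction``).
    * ``radius`` — least-squares circle fit through >= 3 (non-collinear)
      points; exact for 3 points.

    The intensity profile is sampled along the anchor polyline by linear
    interpolation.
    """
    pts = [np.asarray(p, dtype=float) for p in anchors]
    units = ds.geometry.units
    if kind == "distance":
        if len(pts) != 2:
            raise ValueError("distance needs exactly 2 anchor points")
        value = float(np.linalg.norm(pts[1] - pts[0]))
    elif kind == "angle":
        if len(pts) != 3:
            raise ValueError("angle needs exactly 3 anchor points")
        u, v = pts[0] - pts[1], pts[2] - pts[1]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        value = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    elif kind == "caliper":
        if len(pts) != 2 and direction is None:
            raise ValueError("caliper needs 2 anchor points (or an explicit direction)")
        if object_mask is None:
            raise ValueError("caliper requires the object_mask to measure")
        d = np.asarray(direction, float) if direction is not None else pts[1] - pts[0]
        d = d / np.linalg.norm(d)
        zz, yy, xx = np.nonzero(np.asarray(object_mask))
        phys = np.stack([ds.geometry.voxel_center((z, y, x))
                         for z, y, x in zip(zz, yy, xx)])  # (x,y,z)
        proj = phys @ d
        value = float(proj.max() - proj.min())
    elif kind == "radius":
        if len(pts) < 3:
            raise ValueError("radius fit needs >= 3 anchor points")
        value = _circle_fit_radius(pts)
    else:
        raise ValueError(f"unknown measurement kind {kind!r}")
    profile = _intensity_profile(ds, pts)
    return Measurement(kind, tuple(tuple(p) for p in pts), value, units, profile)


def _circle_fit_radius(pts: list[np.ndarray]) -> float:
    p = np.stack(pts)
    # project onto the best plane through the points (SVD); fit in 2-D (Kasa)
    c0 = p.mean(axis=0)
    q = p - c0
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s.size < 2 or s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("anchor points are collinear; no circle fit")
    uv = q @ vt[:2].T
    A = np.column_stack([2 * uv, np.ones(len(uv))])
    b = (uv ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    return float(np.sqrt(c + cx * cx + cy * cy))


def _intensity_profile(ds: LayeredDataset, pts: list[np.ndarray]) -> np.ndarray:
    step = min(ds.geometry.voxel_size)
    img = ds.grayscale()
    dx, dy, dz = ds.geometry.voxel_size
    x0, y0, z0 = ds.geometry.bbox_min
    samples: list[tuple[float, float]] = []
    s_base = 0.0
    for a, b in zip(pts, pts[1:]):
        seg = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(seg / step)), 1)
        for t in np.linspace(0, 1, n + 1)[(1 if samples else 0):]:
            phys = a + t * (b - a)
            vox = [(phys[2] - z0) / dz - 0.5, (phys[1] - y0) / dy - 0.5,
                   (phys[0] - x0) / dx - 0.5]
            val = ndi.map_coordinates(img, np.array(vox)[:, None], order=1,
                                      mode="nearest")[0]
            samples.append((s_base + t * seg, float(val)))
        s_base += seg
    return np.array(samples)


def export_table(table: ObjectTable | Sequence[Measurement], path, format: str = "csv") -> None:
    """Write an object table or measurement list as delimited text.

    One row per object/measurement; the header carries the physical unit
    of every physical column as a ``[unit]`` suffix; numeric cells are
    written at 6 significant digits and round-trip through any delimited
    text reader.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError("format must be 'csv' or 'tsv'")
    if isinstance(table, ObjectTable):
        df = table.df.copy()
        cu = table.column_units()
        df.columns = [f"{c}[{cu[c]}]" if c in cu else c for c in df.columns]
    else:
        df = pd.DataFrame([{"kind": m.kind, f"value[{m.units}]": m.value,
                            "n_anchors": len(m.anchors)} for m in table])
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")
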