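"""Voxel geometry bookkeeping.

Every dataset carries a :class:`VolumeGeometry` describing the physical size
of a voxel and the physical coordinate of the dataset origin (its bounding
box).  Spatial operations (crop, resize, chop, stitching) update the geometry
so that the physical location of the retained data never changes.

Conventions
-----------
* Geometry fields are in semantic ``X, Y, Z`` order: ``voxel_size=(dx, dy, dz)``,
  ``bbox_min=(x0, y0, z0)``.
* Arrays are stored numpy-style ``(z, y, x[, c])``; helpers convert.
* Voxel indices are 0-based with half-open ranges.  The physical centre of
  voxel ``i`` along an axis is ``bbox_min + (i + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = ["VolumeGeometry"]


@dataclass(frozen=True)
class VolumeGeometry:
    """Physical voxel dimensions and bounding box of a volume.

    Parameters
    ----------
    voxel_size : tuple of float
        ``(dx, dy, dz)`` physical units per voxel; all entries must be > 0.
    units : str
        Name of the length unit, e.g. ``"nm"`` or ``"um"``.
    bbox_min : tuple of float
        ``(x0, y0, z0)`` physical coordinate of the dataset origin (the
        low corner of voxel ``(0, 0, 0)``).
    """

    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = "nm"
    bbox_min: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size!r}")
        object.__setattr__(self, "voxel_size", vs)
        bb = tuple(float(v) for v in self.bbox_min)
        if len(bb) != 3:
            raise ValueError("bbox_min must have 3 entries (x0, y0, z0)")
        object.__setattr__(self, "bbox_min", bb)

    # -- axis-order helpers -------------------------------------------------

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel size reordered to match numpy array axes ``(dz, dy, dx)``."""
        dx, dy, dz = self.voxel_size
        return (dz, dy, dx)

    @property
    def origin_zyx(self) -> tuple[float, float, float]:
        x0, y0, z0 = self.bbox_min
        return (z0, y0, x0)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    # -- physical coordinates -----------------------------------------------

    def bbox_max(self, shape_zyx: Sequence[int]) -> tuple[float, float, float]:
        """High corner ``(x1, y1, z1)`` for a volume of the given array shape."""
        nz, ny, nx = shape_zyx[:3]
        dx, dy, dz = self.voxel_size
        x0, y0, z0 = self.bbox_min
        return (x0 + nx * dx, y0 + ny * dy, z0 + nz * dz)

    def extent(self, shape_zyx: Sequence[int]) -> tuple[float, float, float]:
        """Physical extent ``(Lx, Ly, Lz)``."""
        hi = self.bbox_max(shape_zyx)
        return tuple(h - l for h, l in zip(hi, self.bbox_min))

    def voxel_center(self, index_zyx: Sequence[float]) -> tuple[float, float, float]:
        """Physical ``(x, y, z)`` of the centre of voxel ``(z, y, x)``."""
        z, y, x = index_zyx[:3]
        dx, dy, dz = self.voxel_size
        x0, y0, z0 = self.bbox_min
        return (x0 + (x + 0.5) * dx, y0 + (y + 0.5) * dy, z0 + (z + 0.5) * dz)

    # -- transforms ----------------------------------------------------------

    def shifted(self, start_zyx: Sequence[int]) -> "VolumeGeometry":
        """Geometry of a crop/block whose low corner is at voxel ``start_zyx``."""
        z, y, x = start_zyx[:3]
        dx, dy, dz = self.voxel_size
        x0, y0, z0 = self.bbox_min
        return replace(self, bbox_min=(x0 + x * dx, y0 + y * dy, z0 + z * dz))

    def rescaled(self, factor_zyx: Sequence[float]) -> "VolumeGeometry":
        """Geometry after resampling by ``shape_new = shape_old * factor``.

        Voxel size is divided by the factor so the physical extent is
        preserved (halving the grid doubles the voxel).
        """
        fz, fy, fx = factor_zyx[:3]
        dx, dy, dz = self.voxel_size
        return replace(self, voxel_size=(dx / fx, dy / fy, dz / fz))

    def permuted(self, perm_zyx: Sequence[int]) -> "VolumeGeometry":
        """Geometry after transposing array axes by ``perm_zyx`` (z,y,x order)."""
        sp = self.spacing_zyx
        og = self.origin_zyx
        new_sp = tuple(sp[p] for p in perm_zyx)
        new_og = tuple(og[p] for p in perm_zyx)
        return replace(
            self,
            voxel_size=(new_sp[2], new_sp[1], new_sp[0]),
            bbox_min=(new_og[2], new_og[1], new_og[0]),
        )

    def to_dict(self) -> dict:
        return {
            "voxel_size": list(self.voxel_size),
            "units": self.units,
            "bbox_min": list(self.bbox_min),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeGeometry":
        return cls(
            voxel_size=tuple(d.get("voxel_size", (1.0, 1.0, 1.0))),
            units=str(d.get("units", "nm")),
            bbox_min=tuple(d.get("bbox_min", (0.0, 0.0, 0.0))),
        )
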