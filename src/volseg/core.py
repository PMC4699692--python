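"""Four-layer volumetric data model.

A :class:`LayeredDataset` holds the raw ``image`` plus three annotation
layers sharing one spatial grid and one :class:`~volseg.geometry.VolumeGeometry`:

* ``selection`` — the binary working layer that interactive tools write to;
* ``mask`` — an optional binary staging layer used to restrict other
  operations to a region (local thresholding, masked normalisation);
* ``model`` — the final multi-material segmentation, small-integer labels
  described by a :class:`MaterialTable`.

Every mutating operation appends one entry to the dataset's
:class:`ActionLog`; a bounded :class:`HistoryStack` provides undo/redo
independently for 2-D (single-slice) and 3-D (whole-layer) edits.

The module also implements geometry-aware spatial transforms
(:func:`transform`) and lossless volume partitioning (:func:`chop` /
:func:`reassemble`) for block-wise processing of large datasets.
"""

from __future__ import annotations

import copy as _copy
import json
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .geometry import VolumeGeometry

__all__ = [
    "Material",
    "MaterialTable",
    "ActionLog",
    "HistoryStack",
    "LayeredDataset",
    "ChopPlan",
    "transform",
    "undoable_edit",
    "chop",
    "reassemble",
    "register_op",
    "get_op",
]

LAYER_NAMES = ("selection", "mask", "model")
MODEL_DTYPE = np.uint8  # <=255 materials


# ---------------------------------------------------------------------------
# materials


@dataclass(frozen=True)
class Material:
    id: int
    name: str
    color: tuple[int, int, int] = (255, 0, 0)


class MaterialTable:
    """Ordered registry of model materials (id, name, RGB colour).

    Ids are unique and contiguous from 1 (0 is background everywhere);
    names are unique.
    """

    def __init__(self, materials: Iterable[Material | tuple] | None = None):
        self._materials: list[Material] = []
        for m in materials or ():
            if not isinstance(m, Material):
                m = Material(*m)
            self._append(m)

    def _append(self, m: Material) -> None:
        if m.id != len(self._materials) + 1:
            raise ValueError(f"material ids must be contiguous from 1; got id {m.id} at position {len(self._materials)}")
        if m.name in self.names():
            raise ValueError(f"duplicate material name {m.name!r}")
        self._materials.append(m)

    def add(self, name: str, color: tuple[int, int, int] | None = None) -> Material:
        """Register a new material; returns it with the next free id."""
        if len(self._materials) >= 255:
            raise ValueError("material table full (255 materials max for 8-bit models)")
        if color is None:
            palette = [(230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
                       (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230)]
            color = palette[len(self._materials) % len(palette)]
        m = Material(len(self._materials) + 1, name, tuple(color))
        self._append(m)
        return m

    def id_of(self, name: str) -> int:
        for m in self._materials:
            if m.name == name:
                return m.id
        raise KeyError(f"unknown material {name!r}")

    def names(self) -> list[str]:
        return [m.name for m in self._materials]

    def __len__(self) -> int:
        return len(self._materials)

    def __iter__(self):
        return iter(self._materials)

    def __getitem__(self, material_id: int) -> Material:
        if not 1 <= material_id <= len(self._materials):
            raise KeyError(f"no material with id {material_id}")
        return self._materials[material_id - 1]

    def __eq__(self, other) -> bool:
        return isinstance(other, MaterialTable) and self._materials == other._materials

    def copy(self) -> "MaterialTable":
        return MaterialTable(self._materials)

    def to_list(self) -> list[dict]:
        return [{"id": m.id, "name": m.name, "color": list(m.color)} for m in self._materials]

    @classmethod
    def from_list(cls, items: list[dict]) -> "MaterialTable":
        return cls(Material(int(d["id"]), str(d["name"]), tuple(d["color"])) for d in items)


# ---------------------------------------------------------------------------
# action log


@dataclass(frozen=True)
class LogEntry:
    timestamp: float
    operation: str
    params: dict


class ActionLog:
    """Append-only record of every mutating operation applied to a dataset.

    Entries carry the operation name and a JSON-serialisable parameter
    record, so a log can be replayed on the initial data to reproduce the
    final state of any deterministic processing sequence.
    """

    def __init__(self, entries: Iterable[LogEntry] | None = None):
        self._entries: list[LogEntry] = list(entries or ())

    def append(self, operation: str, params: dict | None = None) -> LogEntry:
        entry = LogEntry(time.time(), str(operation), dict(params or {}))
        # ensure the parameter record serialises (fail fast, not at save time)
        json.dumps(entry.params, default=_json_default)
        self._entries.append(entry)
        return entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def __getitem__(self, i):
        return self._entries[i]

    def operations(self) -> list[str]:
        return [e.operation for e in self._entries]

    def copy(self) -> "ActionLog":
        return ActionLog(self._entries)

    def to_list(self) -> list[dict]:
        return [
            {"timestamp": e.timestamp, "operation": e.operation,
             "params": json.loads(json.dumps(e.params, default=_json_default))}
            for e in self._entries
        ]

    @classmethod
    def from_list(cls, items: list[dict]) -> "ActionLog":
        return cls(LogEntry(float(d["timestamp"]), str(d["operation"]), dict(d["params"])) for d in items)

    def replay(self, ds: "LayeredDataset") -> "LayeredDataset":
        """Re-apply every logged operation to ``ds`` via the op registry.

        Only operations registered with :func:`register_op` (all public
        volseg operations) can be replayed; unknown entries raise.
        """
        out = ds
        for e in self._entries:
            fn = get_op(e.operation)
            out = fn(out, **e.params)
        return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


# operation registry used for log replay and recipe execution -----------------

_OP_REGISTRY: dict[str, Callable] = {}


def register_op(name: str, fn: Callable | None = None):
    """Register ``fn`` (signature ``fn(ds, **params) -> LayeredDataset``)
    under ``name`` for ActionLog replay and pipeline recipes."""
    def deco(f):
        _OP_REGISTRY[name] = f
        return f
    return deco(fn) if fn is not None else deco


def get_op(name: str) -> Callable:
    try:
        return _OP_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown operation {name!r}; registered: {sorted(_OP_REGISTRY)}") from None


def registered_ops() -> list[str]:
    return sorted(_OP_REGISTRY)


# ---------------------------------------------------------------------------
# undo history


class HistoryStack:
    """Bounded undo/redo stacks, independent for 2-D and 3-D edit scopes.

    Snapshots store whole affected slices (2-D scope) or the whole layer
    (3-D scope).  Pushing beyond the configured depth evicts the oldest
    snapshot; an undo on an empty stack returns ``False`` rather than
    corrupting state.
    """

    def __init__(self, depth_2d: int = 8, depth_3d: int = 3):
        if depth_2d < 0 or depth_3d < 0:
            raise ValueError("history depths must be >= 0")
        self.depth = {"2d": int(depth_2d), "3d": int(depth_3d)}
        self._undo: dict[str, list] = {"2d": [], "3d": []}
        self._redo: dict[str, list] = {"2d": [], "3d": []}

    def _check(self, scope: str) -> None:
        if scope not in ("2d", "3d"):
            raise ValueError(f"scope must be '2d' or '3d', got {scope!r}")

    def push(self, scope: str, snapshot: Any) -> None:
        self._check(scope)
        if self.depth[scope] == 0:
            return
        stack = self._undo[scope]
        stack.append(snapshot)
        if len(stack) > self.depth[scope]:
            stack.pop(0)
        self._redo[scope].clear()

    def can_undo(self, scope: str) -> bool:
        self._check(scope)
        return bool(self._undo[scope])

    def can_redo(self, scope: str) -> bool:
        self._check(scope)
        return bool(self._redo[scope])

    def pop_undo(self, scope: str, current: Any) -> Any | None:
        self._check(scope)
        if not self._undo[scope]:
            return None
        self._redo[scope].append(current)
        return self._undo[scope].pop()

    def pop_redo(self, scope: str, current: Any) -> Any | None:
        self._check(scope)
        if not self._redo[scope]:
            return None
        self._undo[scope].append(current)
        return self._redo[scope].pop()


# ---------------------------------------------------------------------------
# layered dataset


class LayeredDataset:
    """Image volume plus Selection/Mask/Model layers on one geometry.

    Parameters
    ----------
    image : ndarray
        ``(z, y, x)`` or ``(z, y, x, c)`` unsigned 8/16-bit grid.
    geometry : VolumeGeometry, optional
        Physical voxel size / bounding box (defaults to unit voxels).
    materials : MaterialTable, optional
        Material registry for the model layer.

    Annotation layers are allocated lazily on first access; use
    ``has_mask`` / ``has_model`` / ``has_selection`` to test presence
    without allocating.
    """

    def __init__(
        self,
        image: np.ndarray,
        geometry: VolumeGeometry | None = None,
        materials: MaterialTable | None = None,
        log: ActionLog | None = None,
        history: HistoryStack | None = None,
    ):
        image = np.asarray(image)
        if image.ndim == 2:
            image = image[np.newaxis]
        if image.ndim not in (3, 4):
            raise ValueError(f"image must be (z,y,x) or (z,y,x,c); got shape {image.shape}")
        if image.dtype not in (np.uint8, np.uint16):
            if np.issubdtype(image.dtype, np.integer) and image.min() >= 0 and image.max() <= 255:
                image = image.astype(np.uint8)
            else:
                raise ValueError(f"image dtype must be uint8 or uint16, got {image.dtype}")
        self.image = image
        self.geometry = geometry or VolumeGeometry()
        self.materials = materials or MaterialTable()
        self.log = log or ActionLog()
        self.history = history or HistoryStack()
        self._selection: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._model: np.ndarray | None = None
        #: transient per-pipeline intermediates (not serialized, not copied)
        self.scratch: dict = {}

    # -- shape & dtype -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(nz, ny, nx)``."""
        return self.image.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.image.shape[3] if self.image.ndim == 4 else 1

    @property
    def dtype_max(self) -> int:
        return int(np.iinfo(self.image.dtype).max)

    def grayscale(self) -> np.ndarray:
        """Image as a float64 ``(z, y, x)`` array (channel-averaged if RGB)."""
        img = self.image.astype(np.float64)
        return img.mean(axis=3) if img.ndim == 4 else img

    # -- lazy layers ----------------------------------------------------------

    def _layer(self, attr: str, dtype) -> np.ndarray:
        arr = getattr(self, attr)
        if arr is None:
            arr = np.zeros(self.shape, dtype=dtype)
            setattr(self, attr, arr)
        return arr

    @property
    def selection(self) -> np.ndarray:
        return self._layer("_selection", bool)

    @selection.setter
    def selection(self, arr: np.ndarray) -> None:
        self._set_layer("_selection", arr, bool)

    @property
    def mask(self) -> np.ndarray:
        return self._layer("_mask", bool)

    @mask.setter
    def mask(self, arr: np.ndarray) -> None:
        self._set_layer("_mask", arr, bool)

    @property
    def model(self) -> np.ndarray:
        return self._layer("_model", MODEL_DTYPE)

    @model.setter
    def model(self, arr: np.ndarray) -> None:
        self._set_layer("_model", arr, MODEL_DTYPE)

    def _set_layer(self, attr: str, arr: np.ndarray, dtype) -> None:
        arr = np.asarray(arr)
        if arr.shape != self.shape:
            raise ValueError(f"layer shape {arr.shape} != spatial shape {self.shape}")
        setattr(self, attr, arr.astype(dtype, copy=False))

    @property
    def has_selection(self) -> bool:
        return self._selection is not None

    @property
    def has_mask(self) -> bool:
        return self._mask is not None

    @property
    def has_model(self) -> bool:
        return self._model is not None

    def get_layer(self, name: str) -> np.ndarray:
        if name == "image":
            return self.image
        if name in LAYER_NAMES:
            return getattr(self, name)
        raise KeyError(f"unknown layer {name!r}")

    def set_layer(self, name: str, arr: np.ndarray) -> None:
        if name == "image":
            raise ValueError("segmentation layers only; the image layer is set at construction")
        if name not in LAYER_NAMES:
            raise KeyError(f"unknown layer {name!r}")
        setattr(self, name, arr)

    # -- copying ---------------------------------------------------------------

    def copy(self, share_history: bool = False) -> "LayeredDataset":
        out = LayeredDataset(
            self.image.copy(),
            self.geometry,
            self.materials.copy(),
            self.log.copy(),
            self.history if share_history else HistoryStack(self.history.depth["2d"], self.history.depth["3d"]),
        )
        for attr in ("_selection", "_mask", "_model"):
            arr = getattr(self, attr)
            if arr is not None:
                setattr(out, attr, arr.copy())
        return out

    def _layer_dict(self) -> dict[str, np.ndarray | None]:
        return {"image": self.image, "selection": self._selection,
                "mask": self._mask, "model": self._model}

    def __repr__(self) -> str:
        layers = [n for n in LAYER_NAMES if getattr(self, f"has_{n}")]
        return (f"LayeredDataset(shape={self.shape}, channels={self.n_channels}, "
                f"dtype={self.image.dtype.name}, layers={layers}, "
                f"voxel={self.geometry.voxel_size} {self.geometry.units})")


# ---------------------------------------------------------------------------
# undoable edits


def undoable_edit(
    ds: LayeredDataset,
    edit: Callable[[LayeredDataset], None],
    scope: str = "3d",
    layers: Sequence[str] = ("selection",),
    slice_index: int | None = None,
) -> LayeredDataset:
    """Apply an in-place ``edit`` with an undo snapshot pushed first.

    ``scope='2d'`` snapshots only ``slice_index`` of each named layer;
    ``scope='3d'`` snapshots the whole layer.  Use :func:`undo` /
    :func:`redo` to walk the history.  Mutates and returns ``ds``.
    """
    if scope == "2d" and slice_index is None:
        raise ValueError("2-D scope requires slice_index")
    ds.history.push(scope, _snapshot(ds, scope, layers, slice_index))
    edit(ds)
    ds.log.append("undoable_edit", {"scope": scope, "layers": list(layers),
                                    "slice_index": slice_index})
    return ds


def _snapshot(ds, scope, layers, slice_index):
    snap = {"scope": scope, "slice_index": slice_index, "layers": {}}
    for name in layers:
        arr = ds.get_layer(name)
        snap["layers"][name] = (arr[slice_index].copy() if scope == "2d" else arr.copy())
    return snap


def _restore(ds, snap):
    for name, arr in snap["layers"].items():
        if snap["scope"] == "2d":
            ds.get_layer(name)[snap["slice_index"]] = arr
        else:
            ds.set_layer(name, arr)


def undo(ds: LayeredDataset, scope: str = "3d") -> bool:
    """Undo the most recent edit in ``scope``; ``False`` if nothing to undo."""
    if not ds.history.can_undo(scope):
        return False
    # need the current state of the same layers for redo
    peek = ds.history._undo[scope][-1]
    current = _snapshot(ds, peek["scope"], list(peek["layers"]), peek["slice_index"])
    snap = ds.history.pop_undo(scope, current)
    _restore(ds, snap)
    return True


def redo(ds: LayeredDataset, scope: str = "3d") -> bool:
    """Redo the most recently undone edit in ``scope``."""
    if not ds.history.can_redo(scope):
        return False
    peek = ds.history._redo[scope][-1]
    current = _snapshot(ds, peek["scope"], list(peek["layers"]), peek["slice_index"])
    snap = ds.history.pop_redo(scope, current)
    _restore(ds, snap)
    return True


# ---------------------------------------------------------------------------
# spatial transforms

_AXIS_TO_DIM = {"z": 0, "y": 1, "x": 2}


@register_op("transform")
def transform(ds: LayeredDataset, mode: str, **params) -> LayeredDataset:
    """Geometry-aware spatial transform applied to all four layers.

    Modes
    -----
    ``crop``
        ``x=(lo, hi)``, ``y=...``, ``z=...`` half-open voxel ranges
        (omitted axes keep full extent).  Shifts ``bbox_min``.
    ``resize``
        ``factor=f`` or per-axis ``factor=(fz, fy, fx)``; the image is
        resampled with linear interpolation, annotation layers with
        nearest-neighbour, and ``voxel_size`` is rescaled so the physical
        extent is unchanged.
    ``flip``
        ``axis='x'|'y'|'z'``.
    ``rotate90``
        ``plane='xy'|'xz'|'yz'``, ``k`` quarter-turns.
    ``transpose``
        ``order`` permutation of ``'xyz'`` e.g. ``'zyx'``.

    Returns a new dataset; one log entry is appended.
    """
    if mode == "crop":
        out = _crop(ds, params)
    elif mode == "resize":
        out = _resize(ds, params)
    elif mode == "flip":
        out = _flip(ds, params)
    elif mode == "rotate90":
        out = _rotate90(ds, params)
    elif mode == "transpose":
        out = _transpose(ds, params)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    out.log.append("transform", {"mode": mode, **params})
    return out


def _apply_per_layer(ds: LayeredDataset, fn: Callable[[np.ndarray, bool], np.ndarray],
                     geometry: VolumeGeometry) -> LayeredDataset:
    out = LayeredDataset(fn(ds.image, False), geometry, ds.materials.copy(), ds.log.copy())
    for attr in ("_selection", "_mask", "_model"):
        arr = getattr(ds, attr)
        if arr is not None:
            setattr(out, attr, fn(arr, True))
    return out


def _crop(ds: LayeredDataset, params: dict) -> LayeredDataset:
    nz, ny, nx = ds.shape
    full = {"z": (0, nz), "y": (0, ny), "x": (0, nx)}
    ranges = {}
    for ax, (n0, n1) in full.items():
        lo, hi = params.get(ax, (n0, n1))
        lo, hi = int(lo), int(hi)
        if not (0 <= lo < hi <= n1):
            raise ValueError(f"crop range {ax}=({lo},{hi}) outside volume extent {n1}")
        ranges[ax] = (lo, hi)
    sl = tuple(slice(*ranges[ax]) for ax in ("z", "y", "x"))
    geom = ds.geometry.shifted([ranges["z"][0], ranges["y"][0], ranges["x"][0]])
    return _apply_per_layer(ds, lambda a, _lab: a[sl].copy(), geom)


def _resize(ds: LayeredDataset, params: dict) -> LayeredDataset:
    factor = params.get("factor")
    if factor is None:
        raise ValueError("resize requires factor")
    f = np.atleast_1d(np.asarray(factor, dtype=float))
    if f.size == 1:
        f = np.repeat(f, 3)
    if f.size != 3 or np.any(f <= 0):
        raise ValueError("resize factor must be positive scalar or (fz, fy, fx)")
    new_shape = tuple(max(1, int(round(n * fi))) for n, fi in zip(ds.shape, f))
    actual = np.array(new_shape) / np.array(ds.shape)

    def fn(arr: np.ndarray, is_label: bool) -> np.ndarray:
        zoom = list(actual) + ([1.0] if arr.ndim == 4 else [])
        # labels/binary resized nearest-neighbour only
        order = 0 if is_label else 1
        out = ndi.zoom(arr.astype(np.float64) if not is_label else arr, zoom,
                       order=order, mode="nearest", grid_mode=True)
        if not is_label:
            out = np.clip(np.rint(out), 0, np.iinfo(arr.dtype).max).astype(arr.dtype)
        return out

    return _apply_per_layer(ds, fn, ds.geometry.rescaled(actual))


def _flip(ds: LayeredDataset, params: dict) -> LayeredDataset:
    axis = params.get("axis")
    if axis not in _AXIS_TO_DIM:
        raise ValueError("flip requires axis in {'x','y','z'}")
    dim = _AXIS_TO_DIM[axis]
    return _apply_per_layer(ds, lambda a, _l: np.flip(a, axis=dim).copy(), ds.geometry)


_PLANE_DIMS = {"xy": (2, 1), "xz": (2, 0), "yz": (1, 0)}


def _rotate90(ds: LayeredDataset, params: dict) -> LayeredDataset:
    plane = params.get("plane", "xy")
    k = int(params.get("k", 1))
    if plane not in _PLANE_DIMS:
        raise ValueError("rotate90 plane must be 'xy', 'xz' or 'yz'")
    d0, d1 = _PLANE_DIMS[plane]
    geom = ds.geometry
    if k % 2 == 1:
        perm = [0, 1, 2]
        perm[d0], perm[d1] = perm[d1], perm[d0]
        geom = geom.permuted(perm)
    return _apply_per_layer(ds, lambda a, _l: np.rot90(a, k=k, axes=(d0, d1)).copy(), geom)


def _transpose(ds: LayeredDataset, params: dict) -> LayeredDataset:
    order = params.get("order")
    if order is None or sorted(order) != ["x", "y", "z"]:
        raise ValueError("transpose requires order as a permutation of 'xyz', e.g. 'zxy'")
    # order spells the new semantic axis sequence in x,y,z slots; convert to
    # the numpy (z,y,x) permutation
    new_dims_xyz = [_AXIS_TO_DIM[c] for c in order]  # numpy dim serving as new x,y,z
    perm_zyx = [new_dims_xyz[2], new_dims_xyz[1], new_dims_xyz[0]]

    def fn(arr: np.ndarray, _l: bool) -> np.ndarray:
        axes = perm_zyx + ([3] if arr.ndim == 4 else [])
        return np.transpose(arr, axes).copy()

    return _apply_per_layer(ds, fn, ds.geometry.permuted(perm_zyx))


# ---------------------------------------------------------------------------
# chop / reassemble


@dataclass
class ChopBlock:
    index: tuple[int, int, int]          # (iz, iy, ix) grid position
    core: tuple[tuple[int, int], ...]    # exact-tiling (start, stop) per z,y,x
    extent: tuple[tuple[int, int], ...]  # core expanded by overlap, clipped


@dataclass
class ChopPlan:
    """Block layout of a chopped volume: grid extents + per-block geometry.

    Core ranges tile the source exactly; each block's stored extent is the
    core expanded by ``overlap`` voxels per side (clipped at the volume
    border).  On reassembly overlapping voxels are resolved by plan order:
    the later block wins.
    """

    source_shape: tuple[int, int, int]
    grid: tuple[int, int, int]
    overlap: int
    geometry: VolumeGeometry
    blocks: list[ChopBlock] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "source_shape": list(self.source_shape),
            "grid": list(self.grid),
            "overlap": self.overlap,
            "geometry": self.geometry.to_dict(),
            "blocks": [
                {"index": list(b.index),
                 "core": [list(r) for r in b.core],
                 "extent": [list(r) for r in b.extent]}
                for b in self.blocks
            ],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ChopPlan":
        d = json.loads(text)
        return cls(
            tuple(d["source_shape"]), tuple(d["grid"]), int(d["overlap"]),
            VolumeGeometry.from_dict(d["geometry"]),
            [ChopBlock(tuple(b["index"]),
                       tuple(tuple(r) for r in b["core"]),
                       tuple(tuple(r) for r in b["extent"]))
             for b in d["blocks"]],
        )


def _axis_splits(n: int, parts: int) -> list[tuple[int, int]]:
    """Split [0, n) into ``parts`` near-equal half-open ranges."""
    edges = np.linspace(0, n, parts + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(parts)]


def chop(ds: LayeredDataset, grid: tuple[int, int, int], overlap: int = 0
         ) -> tuple[list[LayeredDataset], ChopPlan]:
    """Divide a dataset into ``grid=(nz, ny, nx)`` blocks for parallel work.

    Each block carries offset geometry so it is a self-contained dataset;
    the returned :class:`ChopPlan` serialises to JSON for re-import.
    """
    grid = tuple(int(g) for g in grid)
    if len(grid) != 3 or any(g < 1 for g in grid):
        raise ValueError("grid counts must be >= 1 per axis")
    if any(g > n for g, n in zip(grid, ds.shape)):
        raise ValueError(f"grid {grid} exceeds shape {ds.shape}")
    overlap = int(overlap)
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    splits = [_axis_splits(n, g) for n, g in zip(ds.shape, grid)]
    min_core = min(min(b - a for a, b in ax) for ax in splits)
    if overlap and overlap >= min_core:
        raise ValueError(f"overlap {overlap} >= smallest block size {min_core}")

    plan = ChopPlan(ds.shape, grid, overlap, ds.geometry)
    blocks: list[LayeredDataset] = []
    for iz in range(grid[0]):
        for iy in range(grid[1]):
            for ix in range(grid[2]):
                core = (splits[0][iz], splits[1][iy], splits[2][ix])
                extent = tuple(
                    (max(0, a - overlap), min(n, b + overlap))
                    for (a, b), n in zip(core, ds.shape)
                )
                plan.blocks.append(ChopBlock((iz, iy, ix), core, extent))
                sl = tuple(slice(a, b) for a, b in extent)
                geom = ds.geometry.shifted([extent[0][0], extent[1][0], extent[2][0]])
                blk = LayeredDataset(ds.image[sl].copy(), geom, ds.materials.copy())
                for attr in ("_selection", "_mask", "_model"):
                    arr = getattr(ds, attr)
                    if arr is not None:
                        setattr(blk, attr, arr[sl].copy())
                blocks.append(blk)
    ds.log.append("chop", {"grid": list(grid), "overlap": overlap})
    return blocks, plan


def reassemble(blocks: Sequence[LayeredDataset], plan: ChopPlan) -> LayeredDataset:
    """Re-compose chopped blocks into one dataset at their plan offsets.

    Overlap-region disagreements are resolved by plan order (later block
    wins).  Material tables are reconciled by name; an unedited
    chop → reassemble round trip is bit-exact.
    """
    if len(blocks) != len(plan.blocks):
        missing = [b.index for b in plan.blocks[len(blocks):]]
        raise ValueError(f"assembly error: expected {len(plan.blocks)} blocks, "
                         f"got {len(blocks)}; missing indices {missing}")
    for blk, meta in zip(blocks, plan.blocks):
        exp_shape = tuple(b - a for a, b in meta.extent)
        if blk.shape != exp_shape:
            raise ValueError(f"block {meta.index} shape {blk.shape} != plan extent {exp_shape}")

    # reconcile materials by name
    materials = MaterialTable()
    remaps: list[dict[int, int]] = []
    for blk in blocks:
        remap = {}
        for m in blk.materials:
            if m.name in materials.names():
                existing = materials[materials.id_of(m.name)]
                if existing.color != m.color:
                    raise ValueError(f"material reconciliation error: {m.name!r} has conflicting colours")
                remap[m.id] = existing.id
            else:
                remap[m.id] = materials.add(m.name, m.color).id
        remaps.append(remap)

    first = blocks[0]
    img_shape = plan.source_shape + ((first.image.shape[3],) if first.image.ndim == 4 else ())
    image = np.zeros(img_shape, dtype=first.image.dtype)
    layers = {n: None for n in LAYER_NAMES}
    for blk, meta, remap in zip(blocks, plan.blocks, remaps):
        sl = tuple(slice(a, b) for a, b in meta.extent)
        image[sl] = blk.image
        for name in LAYER_NAMES:
            if getattr(blk, f"has_{name}"):
                if layers[name] is None:
                    dt = MODEL_DTYPE if name == "model" else bool
                    layers[name] = np.zeros(plan.source_shape, dtype=dt)
                arr = blk.get_layer(name)
                if name == "model" and remap and any(k != v for k, v in remap.items()):
                    arr = _remap_labels(arr, remap)
                layers[name][sl] = arr

    out = LayeredDataset(image, plan.geometry, materials)
    for name, arr in layers.items():
        if arr is not None:
            out.set_layer(name, arr)
    out.log.append("reassemble", {"grid": list(plan.grid), "overlap": plan.overlap})
    return out


def _remap_labels(arr: np.ndarray, remap: dict[int, int]) -> np.ndarray:
    lut = np.arange(256, dtype=MODEL_DTYPE)
    for old, new in remap.items():
        lut[old] = new
    return lut[arr]
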