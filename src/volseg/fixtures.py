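"""Synthetic phantom generators with ground truth.

Every test input in the package is generated here: spherical droplets
(lipid-droplet-like blobs), tubular networks (ER-like), membrane sheets,
a nucleus with a dark envelope, fused sphere pairs, drifting-intensity
stacks and a composite "mitotic cell" phantom combining all organelle
contrast classes on one grid.

Rendering pipeline: a label volume is built first (object priority order),
mapped to class mean intensities, blurred by ~0.7 voxel to emulate
partial-volume softening, then corrupted with Gaussian noise.  The ground
truth is the pre-noise, pre-blur label volume, so phantom recovery scores
measure the segmentation operators, not the renderer.

Default polarity is EM-style (structures darker than a bright background);
``polarity="bright"`` gives the fluorescence-style inverse.  All
generators are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import LayeredDataset, MaterialTable
from .geometry import VolumeGeometry

__all__ = [
    "GroundTruth",
    "make_blobs_phantom",
    "make_two_region_phantom",
    "make_nucleus_phantom",
    "make_network_phantom",
    "make_membrane_phantom",
    "make_fused_pair",
    "make_drift_stack",
    "make_mitotic_phantom",
    "render_tube_network",
]

BG_EM = 180       # bright EM background
BG_LM = 40        # dark fluorescence background
NOISE_FRACTION = 0.05  # default Gaussian sigma as a fraction of dynamic range


@dataclass
class GroundTruth:
    """Pre-noise ideal labels aligned with a phantom.

    ``labels`` uses 0 for background; ``class_names`` maps label values to
    class names; ``objects`` holds per-object records (kind, center zyx,
    size); ``meta`` carries phantom-specific extras (e.g. the analytic
    split plane of a fused pair).
    """

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)
    objects: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def mask_of(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.class_names.items() if v == name]
        if not ids:
            raise KeyError(f"no ground-truth class {name!r}")
        return np.isin(self.labels, ids)


def _finalize(labels: np.ndarray, intensity_of: dict[int, float], background: float,
              rng: np.random.Generator, noise_sigma: float, blur: float = 0.7,
              drift: np.ndarray | None = None,
              geometry: VolumeGeometry | None = None) -> LayeredDataset:
    img = np.full(labels.shape, float(background))
    for lab, mean in intensity_of.items():
        img[labels == lab] = float(mean)
    if blur > 0:
        img = ndi.gaussian_filter(img, blur)
    if drift is not None:
        img += drift[:, None, None]
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LayeredDataset(img, geometry or VolumeGeometry())


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    radii: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return rho2 <= 1.0


def _sphere_mask(shape, center, radius) -> np.ndarray:
    return _ellipsoid_mask(shape, center, (radius,) * 3)


# ---------------------------------------------------------------------------
# blobs


def make_blobs_phantom(
    shape=(64, 64, 64), n=10, radius=(4.0, 8.0), intensity=200, background=50,
    noise_sigma=None, seed=0, min_gap=2.0, voxel_size=(1.0, 1.0, 1.0),
    blur=0.7,
) -> tuple[LayeredDataset, GroundTruth]:
    """Non-overlapping spheres of the given intensity on a flat background.

    Defaults render bright blobs (mean 200) on a dark background (mean 50),
    the graph-cut recovery scenario.  Sphere centres are rejection-sampled
    so that objects never touch (``min_gap`` voxels apart at the surface).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if noise_sigma is None:
        noise_sigma = NOISE_FRACTION * 255
    labels = np.zeros(shape, dtype=np.uint8)
    placed: list[tuple[np.ndarray, float]] = []
    objects = []
    attempts = 0
    while len(placed) < n and attempts < 2000:
        attempts += 1
        r = rng.uniform(*radius) if np.iterable(radius) else float(radius)
        # axes too thin to fit the sphere get a centred cross-section
        c = np.array([rng.uniform(r + 1, s - r - 1) if s > 2 * r + 2 else (s - 1) / 2
                      for s in shape])
        if any(np.linalg.norm(c - pc) < r + pr + min_gap for pc, pr in placed):
            continue
        placed.append((c, r))
        lab = len(placed)
        labels[_sphere_mask(shape, c, r)] = lab
        objects.append({"kind": "sphere", "center": c.tolist(), "radius": r, "label": lab})
    ds = _finalize(labels, {o["label"]: intensity for o in objects}, background,
                   rng, noise_sigma, blur=blur,
                   geometry=VolumeGeometry(voxel_size=voxel_size))
    names = {o["label"]: "blob" for o in objects}
    return ds, GroundTruth(labels, names, objects)


def make_two_region_phantom(shape=(1, 64, 64), split_axis=2, means=(60, 190),
                            noise_sigma=5.0, seed=0) -> tuple[LayeredDataset, GroundTruth]:
    """Two half-volumes of different mean intensity with a sharp boundary."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.uint8)
    idx = [slice(None)] * 3
    idx[split_axis] = slice(shape[split_axis] // 2, None)
    labels[tuple(idx)] = 1
    img = np.where(labels == 1, float(means[1]), float(means[0]))
    img = img + rng.normal(0, noise_sigma, shape)
    ds = LayeredDataset(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return ds, GroundTruth(labels, {1: "bright-half"},
                           meta={"split_axis": split_axis, "split_index": shape[split_axis] // 2})


# ---------------------------------------------------------------------------
# nucleus


def make_nucleus_phantom(shape=(64, 96, 96), radius_fraction=0.33, envelope_width=2.5,
                         interior=150, envelope=50, background=BG_EM,
                         noise_sigma=None, seed=0) -> tuple[LayeredDataset, GroundTruth]:
    """Large ellipsoid with a dark membrane envelope on a bright background.

    Emulates a membrane-enclosed organelle (a nucleus) whose boundary is
    the only strong edge — the one-slice marker-watershed scenario.
    Ground-truth label 1 is the full nucleus (interior + envelope).
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if noise_sigma is None:
        noise_sigma = NOISE_FRACTION * 255
    center = tuple((s - 1) / 2 + rng.uniform(-2, 2) for s in shape)
    radii = tuple(radius_fraction * s for s in shape)
    inner = _ellipsoid_mask(shape, center, tuple(r - envelope_width for r in radii))
    outer = _ellipsoid_mask(shape, center, radii)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[outer] = 1
    img = np.full(shape, float(background))
    img[outer] = float(envelope)
    img[inner] = float(interior)
    img = ndi.gaussian_filter(img, 0.7) + rng.normal(0, noise_sigma, shape)
    ds = LayeredDataset(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    gt = GroundTruth(labels, {1: "nucleus"},
                     objects=[{"kind": "nucleus", "center": center, "radii": radii}])
    return ds, gt


# ---------------------------------------------------------------------------
# tube networks


def render_tube_network(shape, n_segments, radius, rng, margin=4,
                        exclude: np.ndarray | None = None,
                        anisotropy_zyx=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean union of random straight tubes of the given radius.

    Segments connect random endpoint pairs; the tube is the set of voxels
    within ``radius`` (physical, honouring ``anisotropy_zyx``) of a
    rasterized centreline.  ``exclude`` removes centreline voxels (e.g. to
    keep a central region clear) before dilation.
    """
    center_lines = np.zeros(shape, dtype=bool)
    for _ in range(n_segments):
        p0 = np.array([rng.uniform(margin, s - margin) for s in shape])
        p1 = np.array([rng.uniform(margin, s - margin) for s in shape])
        n_steps = int(np.ceil(np.linalg.norm(p1 - p0) * 2)) + 1
        ts = np.linspace(0, 1, n_steps)
        pts = np.rint(p0[None] + ts[:, None] * (p1 - p0)[None]).astype(int)
        pts = np.clip(pts, 0, np.array(shape) - 1)
        center_lines[tuple(pts.T)] = True
    if exclude is not None:
        center_lines &= ~exclude
    dist = ndi.distance_transform_edt(~center_lines, sampling=anisotropy_zyx)
    return dist <= radius


def make_network_phantom(shape=(24, 96, 96), n_segments=14, radius=2.2,
                         intensity=200, background=BG_LM, noise_sigma=None,
                         seed=0) -> tuple[LayeredDataset, GroundTruth]:
    """Bright tubular network on a dark background (fluorescent-ER style).

    The supervoxel-classifier and global-threshold workflow scenario.
    ``meta['n_components']`` records the number of connected network
    components in the ground truth.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if noise_sigma is None:
        noise_sigma = NOISE_FRACTION * 255
    net = render_tube_network(shape, n_segments, radius, rng)
    labels = net.astype(np.uint8)
    ds = _finalize(labels, {1: intensity}, background, rng, noise_sigma)
    n_comp = int(ndi.label(net)[1])
    return ds, GroundTruth(labels, {1: "network"}, meta={"n_components": n_comp})


def make_membrane_phantom(shape=(5, 96, 96), n_curves=6, width=2.0, membrane=60,
                          background=BG_EM, noise_sigma=None, seed=0
                          ) -> tuple[LayeredDataset, GroundTruth]:
    """Thin dark curvilinear membranes on a bright background, per slice.

    Each slice carries smooth sinusoidal curves of ~``width`` px — the
    membrane-detection classifier scenario.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if noise_sigma is None:
        noise_sigma = NOISE_FRACTION * 255
    labels = np.zeros(shape, dtype=np.uint8)
    nz, ny, nx = shape
    for z in range(nz):
        lines = np.zeros((ny, nx), dtype=bool)
        for _ in range(n_curves):
            horizontal = rng.random() < 0.5
            amp = rng.uniform(4, 14)
            per = rng.uniform(30, 80)
            phase = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(8, (ny if horizontal else nx) - 8)
            t = np.arange(nx if horizontal else ny)
            c = off + amp * np.sin(2 * np.pi * t / per + phase)
            ci = np.clip(np.rint(c).astype(int), 0, (ny if horizontal else nx) - 1)
            if horizontal:
                lines[ci, t] = True
            else:
                lines[t, ci] = True
        dist = ndi.distance_transform_edt(~lines)
        labels[z][dist <= width / 2] = 1
    ds = _finalize(labels, {1: membrane}, background, rng, noise_sigma, blur=0.5)
    return ds, GroundTruth(labels, {1: "membrane"})


# ---------------------------------------------------------------------------
# fused pair


def make_fused_pair(radius=10.0, center_distance=14.0, anisotropy=(1.0, 1.0, 1.0),
                    intensity=40, background=BG_EM, noise_sigma=0.0, seed=0,
                    pad=6, axis="x") -> tuple[LayeredDataset, GroundTruth]:
    """Two overlapping spheres rendered as one fused object.

    ``anisotropy`` is the voxel size ``(dx, dy, dz)``; sphere geometry is
    defined in *physical* units, so on anisotropic grids the voxel-space
    footprint is an ellipsoid.  ``axis`` picks the separation direction of
    the two centres — fusing along the coarse axis of an anisotropic grid
    is the case where voxel-space (non-physical) distance transforms fail
    to find the neck.  Ground truth keeps the two spheres separate
    (overlap voxels go to the nearer centre) and records the analytic
    split plane (the perpendicular bisector of the two centres) in
    ``meta['split_plane_vox']`` (voxel index along ``axis``) and
    ``meta['split_plane_phys']`` (physical).
    """
    if not 0 < center_distance < 2 * radius:
        raise ValueError("fused pair requires 0 < center_distance < 2*radius")
    rng = np.random.default_rng(seed)
    dx, dy, dz = anisotropy
    rv = np.array([radius / dz, radius / dy, radius / dx])  # voxel radii zyx
    ax = {"z": 0, "y": 1, "x": 2}[axis]
    step = {"z": dz, "y": dy, "x": dx}[axis]
    sep_vox = center_distance / step
    dims = [int(np.ceil(2 * r)) + 2 * pad for r in rv]
    dims[ax] += int(np.ceil(sep_vox))
    shape = tuple(dims)
    mid = [(n - 1) / 2 for n in shape]
    c0 = list(mid)
    c1 = list(mid)
    c0[ax] -= sep_vox / 2
    c1[ax] += sep_vox / 2
    m0 = _ellipsoid_mask(shape, c0, rv)
    m1 = _ellipsoid_mask(shape, c1, rv)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[m0] = 1
    labels[m1] = 2
    both = m0 & m1
    if both.any():
        pos = np.nonzero(both)
        d0 = (pos[ax] - c0[ax]) ** 2
        d1 = (pos[ax] - c1[ax]) ** 2
        labels[pos] = np.where(d0 <= d1, 1, 2)
    ds = _finalize(labels, {1: intensity, 2: intensity}, background, rng, noise_sigma,
                   geometry=VolumeGeometry(voxel_size=anisotropy))
    split_vox = (c0[ax] + c1[ax]) / 2
    gt = GroundTruth(labels, {1: "sphere", 2: "sphere"},
                     objects=[{"kind": "sphere", "center": tuple(c0), "radius": radius},
                              {"kind": "sphere", "center": tuple(c1), "radius": radius}],
                     meta={"axis": axis, "axis_dim": ax,
                           "split_plane_vox": split_vox,
                           "split_plane_phys": (split_vox + 0.5) * step})
    return ds, gt


# ---------------------------------------------------------------------------
# drifting stack


def make_drift_stack(shape=(12, 48, 48), base_mean=100.0, drift_per_slice=5.0,
                     noise_sigma=4.0, seed=0, with_foreground=False
                     ) -> tuple[LayeredDataset, GroundTruth]:
    """Stack whose slice means ramp linearly — the normalisation scenario.

    With ``with_foreground`` a bright disk of varying size is added per
    slice and the constant background is marked in the ground truth, for
    masked-area normalisation tests.
    """
    rng = np.random.default_rng(seed)
    nz = shape[0]
    drift = np.arange(nz) * float(drift_per_slice)
    labels = np.zeros(shape, dtype=np.uint8)
    if with_foreground:
        for z in range(nz):
            r = 6 + 8 * (z % 3)
            cy, cx = shape[1] // 3, shape[2] // 3
            yy, xx = np.ogrid[: shape[1], : shape[2]]
            labels[z][(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1
    ds = _finalize(labels, {1: base_mean + 90.0}, base_mean, rng, noise_sigma,
                   blur=0.0, drift=drift)
    return ds, GroundTruth(labels, {1: "foreground"}, meta={"drift": drift.tolist()})


# ---------------------------------------------------------------------------
# the composite mitotic-cell phantom


#: class intensity means (uint8, EM polarity: darker = more stained).
#: Darkness order: singular organelles (LD/lysosome/peroxisome) darkest,
#: then ER lumen, then chromosome ~ mitochondria, then background.
MITOTIC_INTENSITY = {
    "er": 60,
    "ld": 25,
    "lysosome": 30,
    "peroxisome": 35,
    "chromosome": 104,
    "mitochondrion": 112,
}

MITOTIC_CLASSES = ("er", "lysosome", "peroxisome", "ld", "chromosome", "mitochondrion")

#: planted radii (voxels) of the three "dark singular object" size classes;
#: the workflow discriminates them by volume after separation.
SINGULAR_RADII = {"ld": 8.0, "lysosome": 5.5, "peroxisome": 3.2}


def make_mitotic_phantom(seed=0, shape=(144, 144, 144), noise_sigma=None,
                         n_ld=6, n_lysosome=6, n_peroxisome=6, n_mito=8,
                         n_er_segments=60, er_radius=2.2
                         ) -> tuple[LayeredDataset, GroundTruth]:
    """Composite phantom of a densely packed mitotic cell.

    Contains, on a bright background: an extensive dark tubular network
    (cytochemically stained ER, lumen mean 60), very dark singular spheres
    in three size classes (lipid droplets r=8, lysosomes r=5.5,
    peroxisomes r=3.2; means 25/30/35), a central irregular dark mass
    (chromosomes, mean 104) whose contrast is deliberately close to the
    medium-dark ellipsoidal mitochondria (mean 112), and Gaussian noise.
    The chromosome mass carries extra speckle texture so that a global
    threshold tuned for the singular organelles also catches part of it —
    the reason the chromosome step needs a local mask.

    Ground-truth classes are mutually disjoint; rendering priority (last
    wins): ER < mitochondria < chromosome < singular organelles.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if noise_sigma is None:
        noise_sigma = NOISE_FRACTION * 255
    nz, ny, nx = shape
    center = np.array([(s - 1) / 2 for s in shape])

    class_ids = {name: i + 1 for i, name in enumerate(MITOTIC_CLASSES)}
    labels = np.zeros(shape, dtype=np.uint8)
    objects: list[dict] = []

    # central chromosome region — keep ER and organelles out of it
    chrom_zone = _sphere_mask(shape, center, 0.24 * min(shape))

    # 1. ER network everywhere outside the chromosome zone
    er = render_tube_network(shape, n_er_segments, er_radius, rng, margin=6,
                             exclude=ndi.binary_dilation(chrom_zone, iterations=3))
    labels[er] = class_ids["er"]

    # 2. mitochondria: medium ellipsoids scattered outside the centre
    placed: list[tuple[np.ndarray, float]] = []
    count = 0
    attempts = 0
    while count < n_mito and attempts < 3000:
        attempts += 1
        radii = np.array([rng.uniform(6, 9), rng.uniform(9, 14), rng.uniform(9, 14)])
        c = np.array([rng.uniform(r + 4, s - r - 4) for r, s in zip(radii, shape)])
        if np.linalg.norm(c - center) < 0.30 * min(shape) + radii.max():
            continue
        if any(np.linalg.norm(c - pc) < radii.max() + pr + 3 for pc, pr in placed):
            continue
        m = _ellipsoid_mask(shape, c, radii)
        labels[m] = class_ids["mitochondrion"]
        placed.append((c, radii.max()))
        objects.append({"kind": "mitochondrion", "center": c.tolist(), "radii": radii.tolist()})
        count += 1

    # 3. chromosome mass: union of overlapping central spheres (irregular)
    chrom = np.zeros(shape, dtype=bool)
    for _ in range(7):
        c = center + rng.uniform(-0.10 * min(shape), 0.10 * min(shape), size=3)
        r = rng.uniform(0.08, 0.13) * min(shape)
        chrom |= _sphere_mask(shape, c, r)
    labels[chrom] = class_ids["chromosome"]
    objects.append({"kind": "chromosome", "center": center.tolist()})

    # 4. dark singular organelles in three size classes
    for name, n_obj in (("ld", n_ld), ("lysosome", n_lysosome), ("peroxisome", n_peroxisome)):
        r = SINGULAR_RADII[name]
        done = 0
        attempts = 0
        while done < n_obj and attempts < 3000:
            attempts += 1
            c = np.array([rng.uniform(r + 3, s - r - 3) for s in shape])
            if np.linalg.norm(c - center) < 0.30 * min(shape) + r:
                continue
            if any(np.linalg.norm(c - pc) < r + pr + 4 for pc, pr in placed):
                continue
            m = _sphere_mask(shape, c, r)
            labels[m] = class_ids[name]
            placed.append((c, r))
            objects.append({"kind": name, "center": c.tolist(), "radius": r})
            done += 1

    intensity_of = {class_ids[k]: v for k, v in MITOTIC_INTENSITY.items()}
    ds = _finalize(labels, intensity_of, BG_EM, rng, noise_sigma)

    # speckle texture inside the chromosome mass: dark puncta that a global
    # dark threshold will catch
    img = ds.image.astype(np.int16)
    speckle = chrom & (rng.random(shape) < 0.04)
    speckle = ndi.binary_dilation(speckle, iterations=1)
    img[speckle] = np.maximum(img[speckle] - 75, 0)
    ds = LayeredDataset(np.clip(img, 0, 255).astype(np.uint8), ds.geometry)

    names = {v: k for k, v in class_ids.items()}
    gt = GroundTruth(labels, names, objects,
                     meta={"background": BG_EM, "intensity": dict(MITOTIC_INTENSITY),
                           "chrom_zone_radius": 0.24 * min(shape),
                           "center": center.tolist()})
    return ds, gt
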