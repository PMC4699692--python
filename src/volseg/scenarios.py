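"""Phantom-recovery evaluation scenarios.

Each function builds a synthetic phantom with known ground truth, runs
one of the package's segmentation engines on it end to end the way an
interactive user would (denoise, place seeds, run, read off the result),
and returns the measured recovery quantities.  They are the package's
standing benchmark: the test suite asserts on their outputs and the
acceptance script reports them.

All randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from scipy import ndimage as ndi

from . import fixtures, segauto
from .core import LayeredDataset
from .filters import DiffusionParams, anisotropic_diffusion
from .pipelines import MITOTIC_MATERIALS, mitotic_cell_workflow

__all__ = [
    "dice",
    "graphcut_blob_recovery",
    "nucleus_watershed_recovery",
    "network_classifier_recovery",
    "membrane_classifier_recovery",
    "fused_pair_separation",
    "mitotic_workflow_recovery",
    "graphcut_oracle_agreement",
    "watershed_oracle_agreement",
    "alignment_recovery",
    "priority_flood_oracle",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    s = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / s) if s else 1.0


# ---------------------------------------------------------------------------
# parameter-recovery scenarios


def graphcut_blob_recovery(seed: int = 0) -> dict:
    """Seeded supervoxel graph-cut of one bright blob in dark background.

    One object stroke through the blob centre and one background stroke
    in a corner; the volume is edge-preservingly denoised before SLIC so
    supervoxel boundaries follow the contrast edge.
    """
    ds, gt = fixtures.make_blobs_phantom(shape=(48, 48, 48), n=1, radius=(9, 11),
                                         seed=seed)
    smooth = anisotropic_diffusion(ds, DiffusionParams(iterations=8, kappa=30),
                                   dims="3d")
    part = segauto.slic(smooth, target_size=16, compactness=0.1)
    seeds = segauto.SeedLabels.empty(ds.shape)
    c = np.array(gt.objects[0]["center"]).astype(int)
    seeds.labels[c[0], c[1], c[2] - 3:c[2] + 4] = segauto.SeedLabels.OBJECT
    seeds.labels[2, 2, 2:20] = segauto.SeedLabels.BACKGROUND
    out = segauto.graphcut_segment(part, seeds)
    return {"dice": dice(out, gt.labels > 0)}


def nucleus_watershed_recovery(seed: int = 0) -> dict:
    """3-D nucleus from two scribbles on a single central slice.

    The marker-controlled watershed floods the gradient relief of a
    dark-envelope nucleus phantom from one interior and one exterior
    scribble placed on the central slice only.
    """
    ds, gt = fixtures.make_nucleus_phantom(seed=seed)
    nz, ny, nx = ds.shape
    seeds = segauto.SeedLabels.empty(ds.shape)
    z = nz // 2
    seeds.labels[z, ny // 2 - 8:ny // 2 + 8, nx // 2 - 8:nx // 2 + 8] = segauto.SeedLabels.OBJECT
    seeds.labels[z, 2:5, :] = segauto.SeedLabels.BACKGROUND
    labels = segauto.watershed_markered(ds, seeds, dims="3d", use_gradient=True)
    return {"dice": dice(labels == 1, gt.mask_of("nucleus"))}


def network_classifier_recovery(seed: int = 0) -> dict:
    """Supervoxel random-forest segmentation of a bright tubular network.

    Mimics classifier use on a fluorescence time-lapse: four frames are
    fully annotated (object + background), a forest is trained on
    per-superpixel intensity features, and the prediction is painted
    across the whole stack.
    """
    ds, gt = fixtures.make_network_phantom(seed=seed)
    net = gt.labels > 0
    annotated = np.zeros(ds.shape, dtype=bool)
    annotated[[2, 8, 14, 20]] = True
    seeds = segauto.SeedLabels.from_masks(net & annotated, ~net & annotated)
    smooth = anisotropic_diffusion(ds, DiffusionParams(iterations=3, kappa=40))
    part = segauto.slic(smooth, target_size=8, compactness=0.1, dims="2d",
                        min_size_factor=0.02)
    binary, clf = segauto.segment_with_supervoxel_classifier(part, seeds, seed=seed)
    return {"dice": dice(binary, net), "training_accuracy": clf.training_accuracy}


def membrane_classifier_recovery(seed: int = 0) -> dict:
    """Per-voxel membrane detection trained on two annotated slices.

    The feature scales start at 0.7 voxels so the ridge filters resolve
    the ~2-px membranes.
    """
    ds, gt = fixtures.make_membrane_phantom(seed=seed)
    mem = gt.labels > 0
    feats = segauto.membrane_features(ds, scales=(0.7, 1.0, 2.0, 4.0))
    labels = np.zeros(ds.shape, dtype=np.uint8)
    labels[:2][mem[:2]] = segauto.SeedLabels.OBJECT
    labels[:2][ndi.distance_transform_edt(~mem[:2]) > 2] = segauto.SeedLabels.BACKGROUND
    clf = segauto.train_classifier(feats, labels, "membrane", n_trees=50, seed=seed)
    _, binary = segauto.predict_classifier(clf, feats)
    return {"dice": dice(binary, mem)}


def fused_pair_separation(seed: int = 0, anisotropic: bool = False) -> dict:
    """Split a fused sphere pair (d = 1.4 r) and locate the cut plane.

    Isotropic grid: r = 10 voxels, fusion along x.  Anisotropic grid:
    voxel (2, 2, 10), r = 20 physical units, fusion along the coarse z
    axis — the case where a voxel-space distance transform misses the
    neck entirely and the physical-units transform is required.
    """
    if anisotropic:
        aniso, axis, r = (2.0, 2.0, 10.0), "z", 20.0
    else:
        aniso, axis, r = (1.0, 1.0, 1.0), "x", 10.0
    ds, gt = fixtures.make_fused_pair(radius=r, center_distance=1.4 * r,
                                      anisotropy=aniso, axis=axis, seed=seed)
    labels = segauto.separate_objects(gt.labels > 0, anisotropy_aware=True,
                                      spacing_zyx=ds.geometry.spacing_zyx,
                                      min_depth=2.0 * min(aniso))
    n = int(labels.max())
    boundary = ndi.binary_dilation(labels == 1) & (labels == 2)
    pos = np.nonzero(boundary)[gt.meta["axis_dim"]]
    err = float(abs(pos.mean() - gt.meta["split_plane_vox"])) if pos.size else float("inf")
    return {"n_objects": n, "split_error_vox": err}


def mitotic_workflow_recovery(seed: int = 0, shape=(144, 144, 144)) -> dict:
    """Run the 13-step workflow on the mitotic phantom and score each class.

    The chromosome-area mask comes from the phantom ground truth dilated
    by a margin (standing in for the brushed + shape-interpolated mask of
    interactive use).  Returns per-class Dice, the ordered log check and
    the final material list.
    """
    ds, gt = fixtures.make_mitotic_phantom(seed=seed, shape=shape)
    central = ndi.binary_dilation(gt.mask_of("chromosome"), iterations=3)
    out, report = mitotic_cell_workflow(ds, central_mask=central)
    res = {f"dice_{name}": dice(out.model == out.materials.id_of(name), gt.mask_of(name))
           for name in MITOTIC_MATERIALS}
    ops = out.log.operations()
    ranks = [int(op.split("step")[1][:2]) for op in ops if op.startswith("mitotic.")]
    res["n_log_steps"] = len(ranks) + sum(op == "anisotropic_diffusion" for op in ops)
    res["log_in_order"] = float(ranks == sorted(ranks) and len(ranks) == 12
                                and ops[0] == "anisotropic_diffusion")
    res["materials"] = out.materials.names()
    return res


# ---------------------------------------------------------------------------
# oracle-equivalence scenarios


def _enumerate_min_cut(n: int, edges: dict, obj_seeds: set, bkg_seeds: set):
    """Brute-force minimum s-t cut over all 2-colourings of n vertices."""
    best_cost, best_sets = np.inf, []
    free = [v for v in range(n) if v not in obj_seeds | bkg_seeds]
    for bits in itertools.product((0, 1), repeat=len(free)):
        side = {v: 1 for v in obj_seeds}
        side.update({v: 0 for v in bkg_seeds})
        side.update(dict(zip(free, bits)))
        cost = sum(w for (i, j), w in edges.items() if side[i] != side[j])
        if cost < best_cost - 1e-12:
            best_cost, best_sets = cost, [side]
        elif abs(cost - best_cost) <= 1e-12:
            best_sets.append(side)
    return best_cost, best_sets


def graphcut_oracle_agreement(n_instances: int = 100, seed: int = 0,
                              max_regions: int = 12) -> dict:
    """Graph-cut vs exhaustive min-cut enumeration on tiny instances.

    Random 2-D images are partitioned into one-voxel supervoxels
    (≤ ``max_regions``), seeded with one object and one background voxel,
    and segmented by the max-flow engine.  The oracle enumerates all
    2-colourings; an instance agrees when the engine's cut cost equals
    the enumerated minimum and the labelling is one of the minimisers.
    """
    rng = np.random.default_rng(seed)
    agreements = 0
    done = 0
    while done < n_instances:
        h = int(rng.integers(2, 4))
        w = int(rng.integers(2, max_regions // h + 1))
        n = h * w
        img = rng.integers(0, 255, size=(1, h, w)).astype(np.float64)
        labels = np.arange(n, dtype=np.int32).reshape(1, h, w)
        part = segauto.SupervoxelPartition(labels, 1, 0.0, n)
        part.stats = {"mean": img.ravel().copy(), "min": img.ravel().copy(),
                      "max": img.ravel().copy()}
        part.adjacency = segauto._adjacency(labels, n)
        obj = int(rng.integers(0, n))
        bkg = int(rng.integers(0, n))
        if obj == bkg:
            continue
        done += 1
        seeds = segauto.SeedLabels.empty((1, h, w))
        seeds.labels.ravel()[obj] = segauto.SeedLabels.OBJECT
        seeds.labels.ravel()[bkg] = segauto.SeedLabels.BACKGROUND
        sigma = 25.0
        out = segauto.graphcut_segment(part, seeds, sigma=sigma)
        side = {v: int(out.ravel()[v]) for v in range(n)}
        mean = part.stats["mean"]
        edges = {}
        for i, nbrs in enumerate(part.adjacency):
            for j in nbrs:
                if j > i:
                    edges[(i, j)] = float(np.exp(-abs(mean[i] - mean[j]) / sigma))
        cost = sum(w_ for (i, j), w_ in edges.items() if side[i] != side[j])
        best_cost, best_sets = _enumerate_min_cut(n, edges, {obj}, {bkg})
        ok = abs(cost - best_cost) <= 1e-9 and side[obj] == 1 and side[bkg] == 0
        agreements += int(ok)
    return {"agreement_rate": agreements / n_instances}


def priority_flood_oracle(relief: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Textbook priority-flood watershed on a 2-D grid (4-connected).

    Independent reference for the marker-controlled watershed: cells are
    popped lowest-relief first and take the label of whichever labelled
    neighbour queued them.
    """
    lab = markers.copy()
    h, w = relief.shape
    heap: list = []
    counter = 0
    visited = markers > 0
    for y, x in zip(*np.nonzero(markers)):
        heapq.heappush(heap, (relief[y, x], counter, y, x, int(markers[y, x])))
        counter += 1
    while heap:
        _, _, y, x, label = heapq.heappop(heap)
        if lab[y, x] == 0:
            lab[y, x] = label
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not visited[ny, nx]:
                visited[ny, nx] = True
                heapq.heappush(heap, (relief[ny, nx], counter, ny, nx, int(lab[y, x])))
                counter += 1
    return lab


def watershed_oracle_agreement(n_instances: int = 100, seed: int = 0) -> dict:
    """Marker watershed vs the priority-flood oracle on ≤12×12 grids.

    Reliefs are smoothed noise with a strict-uniqueness jitter so flood
    order is unambiguous; agreement requires the full label grids to be
    identical.
    """
    rng = np.random.default_rng(seed)
    agreements = 0
    done = 0
    while done < n_instances:
        h, w = (int(v) for v in rng.integers(6, 13, 2))
        relief = ndi.gaussian_filter(rng.normal(size=(h, w)), 1.2)
        relief = relief + rng.permutation(h * w).reshape(h, w) * 1e-9
        p1 = tuple(rng.integers(0, [h, w]))
        p2 = tuple(rng.integers(0, [h, w]))
        if p1 == p2:
            continue
        done += 1
        markers = np.zeros((h, w), np.uint8)
        markers[p1] = segauto.SeedLabels.OBJECT
        markers[p2] = segauto.SeedLabels.BACKGROUND
        seeds = segauto.SeedLabels(markers[np.newaxis])
        ws = segauto.watershed_markered(relief[np.newaxis], seeds, dims="2d")[0]
        pf = priority_flood_oracle(relief, markers.astype(np.int32))
        agreements += int(np.array_equal(ws, pf))
    return {"agreement_rate": agreements / n_instances}


# ---------------------------------------------------------------------------
# alignment


def alignment_recovery(n_shifts: int = 20, seed: int = 0) -> dict:
    """Translation recovery on shifted noisy phantoms (SNR >= 5).

    A 2-D blob phantom is circularly shifted by a random known offset and
    corrupted with 5% noise (contrast/noise ≈ 12); the phase-correlation
    stitcher must place the moving image within ±1 voxel of the true
    offset.  Returns the maximum |error| over all trials and the fraction
    recovered exactly.
    """
    from .imgio import align_translation
    rng = np.random.default_rng(seed)
    base, _ = fixtures.make_blobs_phantom(shape=(1, 64, 64), n=6, radius=(3, 6),
                                          seed=seed, noise_sigma=0)
    img = base.image[0].astype(np.float64)
    sigma = 0.05 * np.ptp(img)
    max_err = 0.0
    exact = 0
    for _ in range(n_shifts):
        dy, dx = (int(v) for v in rng.integers(-10, 11, 2))
        moved = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        fixed = LayeredDataset(np.clip(img + rng.normal(0, sigma, img.shape), 0, 255).astype(np.uint8))
        moving = LayeredDataset(np.clip(moved + rng.normal(0, sigma, img.shape), 0, 255).astype(np.uint8))
        res, _ = align_translation(fixed, moving)
        err = max(abs(res.shift_zyx[1] - (-dy)), abs(res.shift_zyx[2] - (-dx)))
        max_err = max(max_err, float(err))
        exact += int(err == 0)
    return {"max_error_vox": max_err, "exact_fraction": exact / n_shifts}
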