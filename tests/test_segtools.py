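"""Manual tool equivalents: painting, wand, trackers, interpolation, threshold."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi
from skimage.draw import line as skline

from volseg import segauto, segtools
from volseg.core import LayeredDataset
from volseg.fixtures import make_blobs_phantom, make_two_region_phantom
from volseg.geometry import VolumeGeometry
from volseg.segtools import (ClickSequence, ToolStroke, brush, brush_superpixels,
                             line_interpolate, line_track_3d, magic_wand,
                             membrane_track_2d, paint_primitive, region_grow,
                             shape_interpolate, threshold_bw)


@pytest.fixture()
def canvas():
    return LayeredDataset(np.full((8, 32, 32), 128, np.uint8))


class TestPaintPrimitive:
    def test_ball3d_anisotropy_semi_axes(self):
        """Physical 10 nm ball at voxel (5,5,10) nm paints semi-axes (2,2,1)."""
        ds = LayeredDataset(np.zeros((8, 16, 16), np.uint8),
                            VolumeGeometry((5, 5, 10), "nm"))
        paint_primitive(ds, "ball3d", (4, 8, 8), radius=10)
        zz, yy, xx = np.nonzero(ds.selection)
        assert np.ptp(xx) == 4 and np.ptp(yy) == 4  # +-2 voxels
        assert np.ptp(zz) == 2                       # +-1 voxel

    def test_spot_radius_zero_single_voxel(self, canvas):
        paint_primitive(canvas, "spot", (3, 10, 10), radius=0)
        assert canvas.selection.sum() == 1
        assert canvas.selection[3, 10, 10]

    def test_ball_voxel_count_near_sphere_volume(self):
        ds = LayeredDataset(np.zeros((24, 24, 24), np.uint8))
        paint_primitive(ds, "ball3d", (12, 12, 12), radius=6)
        expected = 4 / 3 * np.pi * 6 ** 3
        assert ds.selection.sum() == pytest.approx(expected, rel=0.15)

    def test_tools_never_touch_image_layer(self, canvas):
        before = canvas.image.copy()
        paint_primitive(canvas, "ball3d", (4, 16, 16), radius=5)
        brush(canvas, ToolStroke(((4, 4), (20, 25)), slice_index=2, radius=2))
        assert np.array_equal(canvas.image, before)


class TestBrush:
    def test_distant_points_yield_connected_path(self, canvas):
        brush(canvas, ToolStroke(((2, 3), (29, 27)), slice_index=1, radius=1))
        lab, n = ndi.label(canvas.selection[1],
                           structure=ndi.generate_binary_structure(2, 2))
        assert n == 1

    def test_repeated_stroke_idempotent(self, canvas):
        s = ToolStroke(((5, 5), (5, 20)), slice_index=0, radius=2)
        brush(canvas, s)
        once = canvas.selection.copy()
        brush(canvas, s)
        assert np.array_equal(canvas.selection, once)

    def test_erase_inverts_paint(self, canvas):
        s = ToolStroke(((5, 5), (20, 20)), slice_index=0, radius=3)
        brush(canvas, s)
        brush(canvas, s, mode="erase")
        assert not canvas.selection.any()

    def test_confined_to_slice(self, canvas):
        brush(canvas, ToolStroke(((5, 5), (20, 20)), slice_index=3, radius=2))
        assert canvas.selection[3].any()
        assert not np.delete(canvas.selection, 3, axis=0).any()


class TestBrushSuperpixels:
    @pytest.fixture()
    def two_region(self):
        ds, gt = make_two_region_phantom(shape=(1, 48, 48), seed=4)
        part = segauto.slic(ds, target_size=30, dims="2d")
        return ds, gt, part

    def test_stroke_inside_one_superpixel_selects_it(self, two_region):
        ds, gt, part = two_region
        lab = part.labels[0]
        # pick a superpixel and two interior points well inside it
        target = lab[10, 10]
        ys, xs = np.nonzero(ndi.binary_erosion(lab == target, iterations=1))
        assert len(ys) >= 2
        stroke = ToolStroke(((ys[0], xs[0]), (ys[-1], xs[-1])), slice_index=0, radius=0)
        brush_superpixels(ds, stroke, part)
        assert (lab[ds.selection[0]] == target).all()
        assert ds.selection[0][lab == target].all()

    def test_output_superset_of_plain_brush(self, two_region):
        ds, gt, part = two_region
        stroke = ToolStroke(((5, 5), (30, 40)), slice_index=0, radius=2)
        plain = ds.copy()
        brush(plain, stroke)
        brush_superpixels(ds, stroke, part)
        assert (ds.selection | plain.selection == ds.selection).all()

    def test_respects_contrast_boundary(self, two_region):
        """A stroke in the dark half selects no bright-half voxels."""
        ds, gt, part = two_region
        split = gt.meta["split_index"]
        stroke = ToolStroke(((10, 4), (38, split - 10)), slice_index=0, radius=1)
        brush_superpixels(ds, stroke, part)
        bright = gt.labels[0] == 1
        overlap = (ds.selection[0] & bright).sum() / ds.selection[0].sum()
        assert overlap < 0.02

    def test_missing_partition_instructs_slic(self, canvas):
        with pytest.raises(ValueError, match="SLIC"):
            brush_superpixels(canvas, ToolStroke(((1, 1), (2, 2)), slice_index=0), None)


class TestMagicWand:
    def test_constant_image_selects_everything_3d(self, canvas):
        region = magic_wand(canvas, (4, 16, 16), tolerance=(10, 10), scope="3d")
        assert region.all()

    def test_zero_tolerance_is_iso_intensity_component(self, rng):
        img = rng.integers(0, 4, (1, 16, 16), dtype=np.uint8) * 60
        ds = LayeredDataset(img)
        region = magic_wand(ds, (0, 8, 8), tolerance=(0, 0), scope="2d")
        val = img[0, 8, 8]
        lab, _ = ndi.label(img[0] == val, ndi.generate_binary_structure(2, 2))
        assert np.array_equal(region[0], lab == lab[8, 8])

    def test_diagonal_touch_requires_connectivity_8(self):
        img = np.full((1, 6, 6), 200, np.uint8)
        img[0, 2, 2] = img[0, 3, 3] = 10
        ds = LayeredDataset(img)
        r8 = magic_wand(ds, (0, 2, 2), tolerance=(5, 5), scope="2d", connectivity=8)
        r4 = magic_wand(ds, (0, 2, 2), tolerance=(5, 5), scope="2d", connectivity=4)
        assert r8[0, 3, 3] and not r4[0, 3, 3]

    def test_region_contains_seed_and_is_connected(self, rng):
        img = rng.integers(0, 255, (6, 20, 20), dtype=np.uint8)
        ds = LayeredDataset(img)
        region = magic_wand(ds, (3, 10, 10), tolerance=(40, 40), scope="3d")
        assert region[3, 10, 10]
        lab, n = ndi.label(region, ndi.generate_binary_structure(3, 3))
        assert n == 1


class TestRegionGrow:
    def test_sharp_blob_recovered(self):
        ds, gt = make_blobs_phantom(shape=(32, 32, 32), n=1, radius=(8, 9),
                                    seed=5, noise_sigma=4, blur=0)
        c = tuple(int(v) for v in gt.objects[0]["center"])
        region = region_grow(ds, c, kappa=40)
        m = gt.labels > 0
        dice = 2 * (region & m).sum() / (region.sum() + m.sum())
        assert dice >= 0.95

    def test_zero_kappa_on_noise_stays_at_seed(self, rng):
        img = rng.integers(0, 255, (4, 16, 16), dtype=np.uint8)
        ds = LayeredDataset(img)
        region = region_grow(ds, (2, 8, 8), kappa=0.0)
        assert region.sum() <= 3

    def test_result_same_from_any_seed_in_blob(self):
        ds, gt = make_blobs_phantom(shape=(32, 32, 32), n=1, radius=(8, 9),
                                    seed=5, noise_sigma=4, blur=0)
        c = np.array(gt.objects[0]["center"], dtype=int)
        ref = region_grow(ds, tuple(c), kappa=40)
        for off in ((2, 0, 0), (0, 2, 0), (0, 0, 2), (-2, 0, 0), (0, -2, 0)):
            other = region_grow(ds, tuple(c + off), kappa=40)
            agree = (ref == other).mean()
            assert agree > 0.99


class TestMembraneTracker:
    def test_path_follows_dark_line(self):
        img = np.full((1, 40, 60), 200, np.uint8)
        img[0, 20, 5:55] = 30
        ds = LayeredDataset(img)
        path = membrane_track_2d(ds, ClickSequence(((20, 5), (20, 54)), slice_index=0))
        _, yy, _ = np.nonzero(path)
        assert np.abs(yy - 20).max() <= 1

    def test_adjacent_clicks_give_those_voxels(self, canvas):
        path = membrane_track_2d(canvas, ClickSequence(((5, 5), (5, 6)), slice_index=0))
        assert path[0, 5, 5] and path[0, 5, 6]
        assert path.sum() == 2

    def test_uniform_cost_hugs_straight_chord(self, canvas):
        path = membrane_track_2d(canvas, ClickSequence(((5, 3), (20, 25)), slice_index=0))
        rr, cc = skline(5, 3, 20, 25)
        bres = np.zeros((32, 32), bool)
        bres[rr, cc] = True
        dist = ndi.distance_transform_edt(~bres)
        assert dist[path[0]].max() <= 1.0

    def test_unreachable_corridor_raises(self):
        # corridor 0 keeps only cells exactly on the (non-lattice) chord,
        # which do not form a connected path
        img = np.full((1, 30, 80), 100, np.uint8)
        ds = LayeredDataset(img)
        with pytest.raises(ValueError, match="corridor"):
            membrane_track_2d(ds, ClickSequence(((2, 2), (28, 78)), slice_index=0,
                                                corridor=0))


class TestLineTracker3D:
    def test_identical_xy_anchors_give_vertical_line(self):
        ds = LayeredDataset(np.zeros((10, 16, 16), np.uint8))
        path = line_track_3d(ds, ClickSequence(((0, 8, 8), (9, 8, 8))))
        zz, yy, xx = np.nonzero(path)
        assert len(zz) == 10
        assert (yy == 8).all() and (xx == 8).all()

    def test_helix_rasterized_within_one_voxel(self):
        geom = VolumeGeometry((1, 1, 1))
        ds = LayeredDataset(np.zeros((21, 64, 64), np.uint8), geom)
        t = lambda z: z * 2 * np.pi / 40
        anchors = tuple((z, 32 + 12 * np.sin(t(z)), 32 + 12 * np.cos(t(z)))
                        for z in range(0, 21, 5))
        path = line_track_3d(ds, ClickSequence(anchors))
        for z, y, x in zip(*np.nonzero(path)):
            # compare against the piecewise-linear interpolant of the anchors
            seg = [(a, b) for a, b in zip(anchors, anchors[1:]) if a[0] <= z <= b[0]][0]
            a, b = np.array(seg[0]), np.array(seg[1])
            f = (z - a[0]) / (b[0] - a[0])
            exp = a + f * (b - a)
            assert abs(y - exp[1]) <= 1 and abs(x - exp[2]) <= 1

    def test_physical_interpolation_honours_anisotropy(self):
        """With dz != dx the slice positions differ from voxel-space blending
        only in physical terms — equal z steps still advance x linearly, but
        dilation to a physical radius must produce an anisotropic footprint."""
        geom = VolumeGeometry((1, 1, 4))
        ds = LayeredDataset(np.zeros((9, 32, 32), np.uint8), geom)
        path = line_track_3d(ds, ClickSequence(((0, 16, 16), (8, 16, 16))),
                             radius=4.0)
        zz, yy, xx = np.nonzero(path)
        assert np.ptp(xx) == 8   # +-4 voxels in-plane (1 nm voxels)
        assert np.ptp(zz) == 8   # all 9 slices, but only +-1 beyond endpoints
        mid = path[4]
        assert mid[16, 12] and mid[16, 20]

    def test_same_slice_anchors_rejected(self, canvas):
        with pytest.raises(ValueError, match="same slice"):
            line_track_3d(canvas, ClickSequence(((2, 4, 4), (2, 8, 8))))


def _disk(shape, c, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r * r


class TestShapeInterpolate:
    def test_identical_disks_fixed_point(self):
        layer = np.zeros((5, 32, 32), bool)
        d = _disk((32, 32), (16, 16), 6)
        layer[0] = layer[4] = d
        out = shape_interpolate(layer, 0, 4)
        for k in range(5):
            assert np.array_equal(out[k], d)

    def test_concentric_disks_blend_radius(self):
        layer = np.zeros((3, 40, 40), bool)
        layer[0] = _disk((40, 40), (20, 20), 4)
        layer[2] = _disk((40, 40), (20, 20), 8)
        out = shape_interpolate(layer, 0, 2)
        r_mid = np.sqrt(out[1].sum() / np.pi)
        assert r_mid == pytest.approx(6, abs=1)

    def test_endpoints_reproduced_exactly(self, rng):
        layer = np.zeros((4, 24, 24), bool)
        layer[0] = _disk((24, 24), (10, 9), 5)
        layer[3] = _disk((24, 24), (14, 15), 7)
        a, b = layer[0].copy(), layer[3].copy()
        out = shape_interpolate(layer, 0, 3)
        assert np.array_equal(out[0], a) and np.array_equal(out[3], b)

    def test_symmetric_in_slice_order(self):
        layer = np.zeros((4, 24, 24), bool)
        layer[0] = _disk((24, 24), (10, 9), 5)
        layer[3] = _disk((24, 24), (14, 15), 7)
        fwd = shape_interpolate(layer, 0, 3)
        rev = shape_interpolate(layer[::-1].copy(), 0, 3)[::-1]
        assert np.array_equal(fwd, rev)

    @given(st.integers(3, 9), st.integers(10, 16))
    @settings(max_examples=15, deadline=None)
    def test_area_monotone_for_nested_convex_shapes(self, r_small, r_big):
        layer = np.zeros((6, 40, 40), bool)
        layer[0] = _disk((40, 40), (20, 20), r_small)
        layer[5] = _disk((40, 40), (20, 20), r_big)
        out = shape_interpolate(layer, 0, 5)
        areas = out.reshape(6, -1).sum(axis=1)
        assert (np.diff(areas) >= 0).all()

    def test_unmatched_object_copied_with_warning(self):
        layer = np.zeros((3, 40, 40), bool)
        layer[0] = _disk((40, 40), (10, 10), 4) | _disk((40, 40), (30, 30), 3)
        layer[2] = _disk((40, 40), (10, 10), 4)
        with pytest.warns(UserWarning, match="unmatched"):
            out = shape_interpolate(layer, 0, 2)
        assert out[1][_disk((40, 40), (30, 30), 2)].all()  # lone object persists

    def test_empty_key_slice_rejected(self):
        layer = np.zeros((3, 16, 16), bool)
        layer[0] = _disk((16, 16), (8, 8), 3)
        with pytest.raises(ValueError, match="foreground"):
            shape_interpolate(layer, 0, 2)


class TestLineInterpolate:
    @staticmethod
    def _segment_layer(rows):
        layer = np.zeros((len(rows), 30, 30), bool)
        for k, row in enumerate(rows):
            if row is not None:
                layer[k, row, 5:25] = True
        return layer

    def test_identical_curves_identical_intermediates(self):
        layer = self._segment_layer([10, None, None, 10])
        out = line_interpolate(layer, 0, 3)
        assert np.array_equal(out[1], out[0]) and np.array_equal(out[2], out[0])

    def test_parallel_segments_evenly_spaced(self):
        layer = self._segment_layer([5, None, None, None, 17])
        out = line_interpolate(layer, 0, 4)
        rows = [int(np.nonzero(out[k])[0].mean()) for k in range(5)]
        assert rows == [5, 8, 11, 14, 17]

    def test_arc_length_monotone_between_endpoints(self):
        """Shallow-to-deep sine curves: intermediate Euclidean arc length
        grows monotonically between the two key-curve lengths."""
        layer = np.zeros((4, 64, 64), bool)
        xs = np.arange(4, 60)
        for k, amp in ((0, 2.0), (3, 8.0)):  # max slope <= 1 keeps 1-px curves
            ys = np.rint(32 + amp * np.sin((xs - 4) * 2 * np.pi / 56)).astype(int)
            layer[k, ys, xs] = True

        def euclid_len(plane):
            cols = np.nonzero(plane.any(axis=0))[0]
            ys = [np.nonzero(plane[:, x])[0].mean() for x in cols]
            return float(np.hypot(np.diff(ys), np.diff(cols)).sum())

        out = line_interpolate(layer, 0, 3)
        lengths = [euclid_len(out[k]) for k in range(4)]
        assert lengths[0] < lengths[3]
        assert (np.diff(lengths) >= -0.5).all()  # monotone up to rasterization

    def test_branching_curve_rejected(self):
        layer = np.zeros((3, 20, 20), bool)
        layer[0, 10, 2:18] = True
        layer[0, 2:10, 10] = True  # T-junction
        layer[2, 5, 2:18] = True
        with pytest.raises(ValueError, match="branch"):
            line_interpolate(layer, 0, 2)


class TestThreshold:
    def test_full_range_selects_everything(self, canvas):
        out = threshold_bw(canvas, (0, 255))
        assert out.selection.all()

    def test_masked_scope_subset_of_mask(self, rng):
        img = rng.integers(0, 255, (4, 24, 24), dtype=np.uint8)
        ds = LayeredDataset(img)
        ds.mask = rng.random((4, 24, 24)) > 0.5
        out = threshold_bw(ds, (0, 128), scope="masked")
        assert not (out.selection & ~ds.mask).any()

    def test_bimodal_phantom_dark_class_accuracy(self, rng):
        truth = rng.random((8, 32, 32)) > 0.5
        img = np.where(truth, 200.0, 50.0) + rng.normal(0, 10, truth.shape)
        ds = LayeredDataset(np.clip(img, 0, 255).astype(np.uint8))
        out = threshold_bw(ds, (0, 125))
        acc = (out.selection == ~truth).mean()
        assert acc >= 0.99

    def test_window_inclusive_both_ends(self):
        ds = LayeredDataset(np.array([[[10, 11, 20, 21]]], dtype=np.uint8))
        out = threshold_bw(ds, (11, 20))
        assert list(out.selection[0, 0]) == [False, True, True, False]

    def test_inverted_window_rejected(self, canvas):
        with pytest.raises(ValueError, match="low"):
            threshold_bw(canvas, (100, 50))
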