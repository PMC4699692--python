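"""Four-layer data model: geometry bookkeeping, transforms, undo, chop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volseg import core
from volseg.core import (ActionLog, ChopPlan, HistoryStack, LayeredDataset,
                         MaterialTable, chop, reassemble, redo, transform, undo,
                         undoable_edit)
from volseg.geometry import VolumeGeometry


# ---------------------------------------------------------------------------
# geometry


class TestVolumeGeometry:
    def test_invalid_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            VolumeGeometry((0, 1, 1))
        with pytest.raises(ValueError):
            VolumeGeometry((1, -2, 1))

    def test_bbox_extent_matches_shape_times_voxel(self):
        g = VolumeGeometry((5, 5, 20), "nm", (10, 20, 30))
        assert g.extent((4, 8, 6)) == (30.0, 40.0, 80.0)
        assert g.bbox_max((4, 8, 6)) == (40.0, 60.0, 110.0)

    def test_voxel_center_half_voxel_convention(self):
        g = VolumeGeometry((2, 2, 2), "nm", (0, 0, 0))
        assert g.voxel_center((0, 0, 0)) == (1.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# materials / log


class TestMaterialTable:
    def test_ids_contiguous_and_names_unique(self):
        mt = MaterialTable()
        a = mt.add("er")
        b = mt.add("mito")
        assert (a.id, b.id) == (1, 2)
        with pytest.raises(ValueError):
            mt.add("er")

    def test_serialisation_round_trip(self):
        mt = MaterialTable()
        mt.add("x", (1, 2, 3))
        assert MaterialTable.from_list(mt.to_list()) == mt


def test_action_log_replay_reproduces_dataset(small_ds):
    """Replaying the log on the pristine input reproduces the final state."""
    out = transform(small_ds, "crop", x=(2, 18), z=(1, 11))
    out = transform(out, "flip", axis="y")
    out = transform(out, "rotate90", plane="xy", k=1)
    replayed = ActionLog(out.log).replay(small_ds)
    assert np.array_equal(replayed.image, out.image)
    assert replayed.geometry == out.geometry


# ---------------------------------------------------------------------------
# transforms


class TestTransform:
    def test_crop_shifts_bbox(self):
        img = np.zeros((30, 30, 30), np.uint8)
        ds = LayeredDataset(img, VolumeGeometry((5, 5, 5), "nm"))
        out = transform(ds, "crop", x=(10, 20))
        assert out.shape == (30, 30, 10)
        assert out.geometry.bbox_min == (50.0, 0.0, 0.0)

    def test_crop_out_of_bounds_rejected(self, small_ds):
        with pytest.raises(ValueError):
            transform(small_ds, "crop", x=(5, 25))

    def test_flip_is_involution_on_all_layers(self, small_ds):
        small_ds.selection = small_ds.image > 128
        small_ds.model = (small_ds.image > 200).astype(np.uint8)
        out = transform(transform(small_ds, "flip", axis="x"), "flip", axis="x")
        assert np.array_equal(out.image, small_ds.image)
        assert np.array_equal(out.selection, small_ds.selection)
        assert np.array_equal(out.model, small_ds.model)
        assert out.geometry == small_ds.geometry

    def test_resize_preserves_physical_extent(self):
        """Halving the grid doubles the voxel so the physical bbox is unchanged."""
        img = np.zeros((40, 40, 40), np.uint8)
        ds = LayeredDataset(img, VolumeGeometry((5, 5, 5), "nm"))
        out = transform(ds, "resize", factor=0.5)
        assert out.shape == (20, 20, 20)
        assert out.geometry.voxel_size == (10.0, 10.0, 10.0)
        assert out.geometry.extent(out.shape) == ds.geometry.extent(ds.shape)

    def test_resize_labels_stay_integral(self, small_ds):
        small_ds.model = (small_ds.image % 3).astype(np.uint8)
        out = transform(small_ds, "resize", factor=2.0)
        assert set(np.unique(out.model)) <= set(np.unique(small_ds.model))

    def test_rotate90_swaps_in_plane_voxel_sizes(self, small_ds):
        out = transform(small_ds, "rotate90", plane="xz", k=1)
        dx, dy, dz = small_ds.geometry.voxel_size
        assert out.geometry.voxel_size == (dz, dy, dx)

    def test_transpose_permutes_shape_and_geometry(self, small_ds):
        out = transform(small_ds, "transpose", order="zyx")
        assert out.shape == small_ds.shape[::-1]
        dx, dy, dz = small_ds.geometry.voxel_size
        assert out.geometry.voxel_size == (dz, dy, dx)

    def test_marked_voxel_center_invariant_under_crop(self, small_ds):
        """The physical position of a voxel survives crop bookkeeping."""
        mark = (5, 7, 9)
        before = small_ds.geometry.voxel_center(mark)
        out = transform(small_ds, "crop", x=(4, 15), y=(2, 16), z=(3, 12))
        after = out.geometry.voxel_center((mark[0] - 3, mark[1] - 2, mark[2] - 4))
        assert before == pytest.approx(after)

    def test_every_transform_appends_one_log_entry(self, small_ds):
        n0 = len(small_ds.log)
        out = transform(small_ds, "flip", axis="z")
        assert len(out.log) == n0 + 1
        assert out.log[-1].operation == "transform"

    @given(st.lists(st.sampled_from(["flipx", "flipy", "rot", "transpose"]),
                    min_size=1, max_size=6))
    @settings(max_examples=25, deadline=None)
    def test_layer_shape_congruence_over_random_sequences(self, ops):
        """All four layers keep identical spatial shape after any op sequence."""
        rng = np.random.default_rng(1)
        ds = LayeredDataset(rng.integers(0, 255, (6, 8, 10), dtype=np.uint8),
                            VolumeGeometry((1, 2, 3)))
        ds.selection = ds.image > 100
        ds.mask = ds.image > 50
        ds.model = (ds.image % 4).astype(np.uint8)
        for op in ops:
            if op == "flipx":
                ds = transform(ds, "flip", axis="x")
            elif op == "flipy":
                ds = transform(ds, "flip", axis="y")
            elif op == "rot":
                ds = transform(ds, "rotate90", plane="xy", k=1)
            else:
                ds = transform(ds, "transpose", order="zxy")
            for layer in (ds.selection, ds.mask, ds.model):
                assert layer.shape == ds.shape
            # bbox extent stays consistent with shape x voxel size
            ext = ds.geometry.extent(ds.shape)
            dx, dy, dz = ds.geometry.voxel_size
            nz, ny, nx = ds.shape
            assert ext == pytest.approx((nx * dx, ny * dy, nz * dz))


# ---------------------------------------------------------------------------
# undo history


class TestUndo:
    def test_edit_then_undo_restores_bit_identical(self, small_ds):
        before = small_ds.selection.copy()
        undoable_edit(small_ds, lambda d: d.selection.__setitem__(slice(None), True),
                      scope="3d")
        assert small_ds.selection.all()
        assert undo(small_ds, "3d")
        assert np.array_equal(small_ds.selection, before)

    def test_undo_then_redo_restores_pre_undo_state(self, small_ds):
        undoable_edit(small_ds, lambda d: d.selection.__setitem__((0,), True),
                      scope="2d", slice_index=0)
        after_edit = small_ds.selection.copy()
        undo(small_ds, "2d")
        redo(small_ds, "2d")
        assert np.array_equal(small_ds.selection, after_edit)

    def test_bounded_depth_evicts_oldest(self):
        ds = LayeredDataset(np.zeros((4, 4, 4), np.uint8))
        ds.history = HistoryStack(depth_2d=8, depth_3d=2)
        for i in range(3):
            undoable_edit(ds, lambda d, i=i: d.selection.__setitem__((i,), True),
                          scope="3d")
        assert undo(ds, "3d") and undo(ds, "3d")
        assert not undo(ds, "3d")  # third snapshot was evicted

    def test_undo_on_empty_stack_is_explicit_noop(self, small_ds):
        assert undo(small_ds, "3d") is False
        assert undo(small_ds, "2d") is False

    def test_2d_and_3d_scopes_undo_independently(self, small_ds):
        """Per-scope stacks: undoing one scope leaves the other scope's
        edits (on other slices) in place, matching a log-replay oracle."""
        # 2-D edit on slice 0; 3-D edit on the remaining slices
        undoable_edit(small_ds, lambda d: d.selection.__setitem__((0,), True),
                      scope="2d", slice_index=0)
        undoable_edit(small_ds,
                      lambda d: d.selection.__setitem__((slice(1, None), 3), True),
                      scope="3d")
        assert undo(small_ds, "2d")              # removes only the slice edit
        oracle = np.zeros(small_ds.shape, bool)  # replay just the 3-D edit
        oracle[1:, 3] = True
        assert np.array_equal(small_ds.selection, oracle)
        # undoing the 3-D edit restores the snapshot taken after the 2-D
        # edit (whole-layer snapshot semantics)
        assert undo(small_ds, "3d")
        only_2d = np.zeros(small_ds.shape, bool)
        only_2d[0] = True
        assert np.array_equal(small_ds.selection, only_2d)


# ---------------------------------------------------------------------------
# chop / reassemble


class TestChop:
    def test_grid_tiles_shapes_and_offsets(self):
        ds = LayeredDataset(np.zeros((16, 64, 64), np.uint8), VolumeGeometry((2, 2, 2)))
        blocks, plan = chop(ds, (1, 2, 2), overlap=0)
        assert len(blocks) == 4
        assert all(b.shape == (16, 32, 32) for b in blocks)
        assert blocks[1].geometry.bbox_min == (64.0, 0.0, 0.0)  # x-offset 32 vox * 2 nm

    def test_single_block_chop_is_identity(self, small_ds):
        blocks, plan = chop(small_ds, (1, 1, 1))
        assert np.array_equal(blocks[0].image, small_ds.image)
        assert blocks[0].geometry == small_ds.geometry

    def test_block_union_covers_every_voxel_exactly(self, rng):
        ds = LayeredDataset(rng.integers(0, 255, (7, 9, 11), dtype=np.uint8))
        blocks, plan = chop(ds, (2, 3, 2), overlap=0)
        count = np.zeros(ds.shape, np.int32)
        for meta in plan.blocks:
            sl = tuple(slice(a, b) for a, b in meta.extent)
            count[sl] += 1
        assert (count == 1).all()

    @pytest.mark.parametrize("grid,overlap", [((2, 2, 2), 0), ((1, 3, 2), 0),
                                              ((2, 2, 2), 1), ((1, 2, 2), 2)])
    def test_chop_reassemble_is_bit_exact(self, rng, grid, overlap):
        ds = LayeredDataset(rng.integers(0, 255, (12, 14, 16), dtype=np.uint8),
                            VolumeGeometry((1, 2, 3), "nm", (4, 5, 6)))
        ds.selection = ds.image > 100
        ds.model = (ds.image % 3).astype(np.uint8)
        blocks, plan = chop(ds, grid, overlap=overlap)
        back = reassemble(blocks, plan)
        assert np.array_equal(back.image, ds.image)
        assert np.array_equal(back.selection, ds.selection)
        assert np.array_equal(back.model, ds.model)
        assert back.geometry == ds.geometry

    def test_plan_serialises_and_restores(self, small_ds):
        blocks, plan = chop(small_ds, (2, 2, 2), overlap=1)
        plan2 = ChopPlan.from_json(plan.to_json())
        back = reassemble(blocks, plan2)
        assert np.array_equal(back.image, small_ds.image)

    def test_overlap_conflict_later_block_wins(self):
        ds = LayeredDataset(np.zeros((4, 4, 8), np.uint8))
        blocks, plan = chop(ds, (1, 1, 2), overlap=1)
        # both blocks edit the shared overlap column differently
        blocks[0].selection[..., -1] = True   # overlap zone, first block
        blocks[1].selection[:] = False
        back = reassemble(blocks, plan)
        # overlap column belongs to the later block -> stays False
        assert not back.selection.any()

    def test_missing_block_raises_with_indices(self, small_ds):
        blocks, plan = chop(small_ds, (2, 1, 1))
        with pytest.raises(ValueError, match="missing"):
            reassemble(blocks[:1], plan)

    def test_overlap_larger_than_block_rejected(self, small_ds):
        with pytest.raises(ValueError):
            chop(small_ds, (4, 4, 4), overlap=5)

    def test_material_tables_reconciled_by_name(self, small_ds):
        blocks, plan = chop(small_ds, (1, 1, 2))
        blocks[0].materials.add("er")
        blocks[1].materials.add("mito")
        blocks[1].model[0, 0, 0] = 1
        back = reassemble(blocks, plan)
        assert back.materials.names() == ["er", "mito"]
        # block 1's label 1 ("mito") was remapped to the merged id 2
        assert back.model[0, 0, small_ds.shape[2] // 2] == 2
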