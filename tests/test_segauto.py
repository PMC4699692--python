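"""Semiautomatic engines: SLIC, graph-cut, watershed, separation, classifiers."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from volseg import scenarios, segauto
from volseg.core import LayeredDataset
from volseg.fixtures import (make_blobs_phantom, make_fused_pair,
                             make_membrane_phantom, make_two_region_phantom)
from volseg.segauto import (FeatureStack, SeedLabels, TrainedClassifier,
                            graphcut_segment, membrane_features,
                            predict_classifier, separate_objects, slic,
                            supervoxel_features, train_classifier,
                            watershed_markered)


class TestSLIC:
    def test_constant_image_regular_tiling_equal_means(self):
        ds = LayeredDataset(np.full((8, 32, 32), 100, np.uint8))
        part = slic(ds, target_size=64)
        assert part.n_regions > 1
        assert np.allclose(part.stats["mean"], 100.0)

    def test_every_voxel_labelled_contiguously(self, blob_phantom):
        ds, _ = blob_phantom
        part = slic(ds, target_size=100)
        labs = np.unique(part.labels)
        assert labs[0] == 0 and labs[-1] == part.n_regions - 1
        assert len(labs) == part.n_regions

    def test_region_count_within_factor_two_of_request(self, blob_phantom):
        ds, _ = blob_phantom
        target = 100
        part = slic(ds, target_size=target)
        requested = ds.image.size // target
        assert requested / 2 <= part.n_regions <= requested * 2

    def test_adjacency_symmetric(self, blob_phantom):
        ds, _ = blob_phantom
        part = slic(ds, target_size=200)
        for i, nbrs in enumerate(part.adjacency):
            for j in nbrs:
                assert i in part.adjacency[j]

    def test_boundary_recall_on_two_region_phantom(self):
        """Standard boundary recall: >= 95% of true edge pixels lie within
        2 px of a superpixel boundary."""
        from skimage.segmentation import find_boundaries
        ds, gt = make_two_region_phantom(shape=(1, 64, 64), seed=1)
        part = slic(ds, target_size=60, dims="2d")
        sp_edges = find_boundaries(part.labels[0], mode="thick")
        near_edge = ndi.binary_dilation(sp_edges, iterations=2)
        edge_x = gt.meta["split_index"]
        recall = near_edge[:, edge_x].mean()
        assert recall >= 0.95

    def test_deterministic(self, blob_phantom):
        ds, _ = blob_phantom
        a = slic(ds, target_size=100)
        b = slic(ds, target_size=100)
        assert np.array_equal(a.labels, b.labels)

    def test_tiny_target_rejected(self, blob_phantom):
        ds, _ = blob_phantom
        with pytest.raises(ValueError, match="target_size"):
            slic(ds, target_size=4)


class TestGraphCut:
    def test_matches_exhaustive_min_cut_enumeration(self):
        """Engine cut cost equals brute-force enumeration over all
        2-colourings on 100 random <=12-supervoxel instances."""
        res = scenarios.graphcut_oracle_agreement(100, seed=7)
        assert res["agreement_rate"] == 1.0

    def test_blob_recovery_dice(self):
        assert scenarios.graphcut_blob_recovery(seed=0)["dice"] >= 0.95

    def test_all_object_seeds_give_everything(self, blob_phantom):
        ds, _ = blob_phantom
        part = slic(ds, target_size=200)
        seeds = SeedLabels.empty(ds.shape)
        seeds.labels[:] = SeedLabels.OBJECT
        seeds.labels[0, 0, 0] = SeedLabels.BACKGROUND
        with pytest.raises(ValueError, match="both classes"):
            # every supervoxel is object-seeded except one shared corner
            graphcut_segment(part, seeds)

    def test_seeded_regions_stay_on_their_side(self, blob_phantom):
        ds, gt = blob_phantom
        part = slic(ds, target_size=100)
        seeds = SeedLabels.empty(ds.shape)
        c = np.array(gt.objects[0]["center"], dtype=int)
        seeds.labels[tuple(c)] = SeedLabels.OBJECT
        seeds.labels[0, 0, 0] = SeedLabels.BACKGROUND
        out = graphcut_segment(part, seeds)
        assert out[tuple(c)]
        assert not out[0, 0, 0]

    def test_cut_topology_invariant_to_sigma_rescaling(self):
        """On the blob phantom the segmented set is stable across a sigma
        grid spanning one decade."""
        ds, gt = make_blobs_phantom(shape=(32, 32, 32), n=1, radius=(8, 9), seed=2,
                                    noise_sigma=5, blur=0)
        part = slic(ds, target_size=30, compactness=0.1)
        seeds = SeedLabels.empty(ds.shape)
        c = np.array(gt.objects[0]["center"], dtype=int)
        seeds.labels[c[0], c[1] - 2:c[1] + 3, c[2]] = SeedLabels.OBJECT
        seeds.labels[1, 1, 1:12] = SeedLabels.BACKGROUND
        outs = [graphcut_segment(part, seeds, sigma=s) for s in (10, 20, 40)]
        assert np.array_equal(outs[0], outs[1])
        assert np.array_equal(outs[1], outs[2])

    def test_conflicting_seeds_in_one_supervoxel_rejected(self):
        ds = LayeredDataset(np.full((4, 16, 16), 90, np.uint8))
        part = slic(ds, target_size=256)
        seeds = SeedLabels.empty(ds.shape)
        seeds.labels[0, 0, 0] = SeedLabels.OBJECT
        seeds.labels[0, 0, 1] = SeedLabels.BACKGROUND
        if part.region_of((0, 0, 0)) == part.region_of((0, 0, 1)):
            with pytest.raises(ValueError, match="both classes"):
                graphcut_segment(part, seeds)


class TestWatershed:
    def test_matches_priority_flood_oracle(self):
        res = scenarios.watershed_oracle_agreement(100, seed=7)
        assert res["agreement_rate"] == 1.0

    def test_two_basin_relief_partition(self):
        yy, xx = np.mgrid[0:10, 0:10].astype(float)
        relief = np.minimum((xx - 2) ** 2 + (yy - 5) ** 2,
                            (xx - 7) ** 2 + (yy - 5) ** 2)
        markers = np.zeros((10, 10), np.uint8)
        markers[5, 2] = SeedLabels.OBJECT
        markers[5, 7] = SeedLabels.BACKGROUND
        seeds = SeedLabels(markers[np.newaxis])
        out = watershed_markered(relief[np.newaxis], seeds, dims="2d")[0]
        oracle = scenarios.priority_flood_oracle(relief, markers.astype(np.int32))
        assert np.array_equal(out, oracle)

    def test_nucleus_from_single_slice_scribbles(self):
        assert scenarios.nucleus_watershed_recovery(seed=0)["dice"] >= 0.9

    def test_extra_background_marker_never_enlarges_object(self):
        from volseg.fixtures import make_nucleus_phantom
        ds, gt = make_nucleus_phantom(shape=(32, 48, 48), seed=3)
        seeds = SeedLabels.empty(ds.shape)
        z = 16
        seeds.labels[z, 20:28, 20:28] = SeedLabels.OBJECT
        seeds.labels[z, 2:5, :] = SeedLabels.BACKGROUND
        base = (watershed_markered(ds, seeds, use_gradient=True) == 1).sum()
        seeds.labels[z, :, 2:5] = SeedLabels.BACKGROUND  # extra bkg scribble
        more = (watershed_markered(ds, seeds, use_gradient=True) == 1).sum()
        assert more <= base

    def test_single_class_markers_rejected(self):
        seeds = SeedLabels.empty((2, 8, 8))
        seeds.labels[0, 0, 0] = SeedLabels.OBJECT
        with pytest.raises(ValueError, match="both"):
            watershed_markered(np.zeros((2, 8, 8)), seeds)


class TestSeparateObjects:
    def test_fused_pair_split_at_bisector(self):
        res = scenarios.fused_pair_separation(seed=0, anisotropic=False)
        assert res["n_objects"] == 2
        assert res["split_error_vox"] <= 2.0

    def test_single_sphere_not_oversplit(self):
        ds, gt = make_blobs_phantom(shape=(40, 40, 40), n=1, radius=(10, 10), seed=2)
        labels = separate_objects(gt.labels > 0, min_depth=2.0)
        assert labels.max() == 1

    def test_anisotropic_split_needs_physical_distances(self):
        ds, gt = make_fused_pair(radius=20, center_distance=28,
                                 anisotropy=(2, 2, 10), axis="z")
        spacing = ds.geometry.spacing_zyx
        aware = separate_objects(gt.labels > 0, anisotropy_aware=True,
                                 spacing_zyx=spacing, min_depth=4.0)
        naive = separate_objects(gt.labels > 0, anisotropy_aware=False,
                                 min_depth=1.0)
        assert aware.max() == 2
        assert naive.max() == 1  # voxel-space distances miss the neck

    def test_never_merges_disconnected_components(self, rng):
        blobs = np.zeros((24, 24, 24), bool)
        blobs[4:8, 4:8, 4:8] = True
        blobs[14:20, 14:20, 14:20] = True
        blobs[2, 20, 2] = True  # tiny isolated voxel
        labels = separate_objects(blobs, min_depth=2.0)
        n_in = ndi.label(blobs)[1]
        assert labels.max() >= n_in
        # each input component maps to a distinct set of output labels
        comp, _ = ndi.label(blobs)
        for c in range(1, n_in + 1):
            got = set(np.unique(labels[comp == c])) - {0}
            assert got, f"component {c} lost"
            for other in range(1, n_in + 1):
                if other != c:
                    assert not got & (set(np.unique(labels[comp == other])) - {0})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            separate_objects(np.zeros((4, 4, 4), bool))


class TestMembraneFeatures:
    def test_constant_image_zero_derivative_features(self):
        fs = membrane_features(np.full((1, 24, 24), 99.0), scales=(1.0, 2.0))
        deriv_cols = [i for i, n in enumerate(fs.names)
                      if n.startswith(("gradmag", "hess", "dog"))]
        assert np.abs(fs.data[..., deriv_cols]).max() < 1e-9

    def test_dark_line_ridge_polarity(self):
        img = np.full((1, 32, 32), 200.0)
        img[0, 16, 4:28] = 60.0
        fs = membrane_features(img, scales=(1.0, 2.0))
        e1 = fs.data[0, :, :, fs.names.index("hess_e1_1")]
        assert e1[16, 16] > e1[8, 16]  # dark ridge: leading eigenvalue positive

    def test_feature_count_matches_schema(self):
        scales = (1.0, 2.0, 4.0)
        fs = membrane_features(np.zeros((1, 8, 8)), context_radius=5, scales=scales)
        expected = 1 + 4 * len(scales) + (len(scales) - 1) + 6
        assert fs.data.shape[-1] == expected == len(fs.names)
        assert f"f={expected}" in fs.schema_id


class TestSupervoxelFeatures:
    def test_constant_image_identical_rows(self):
        ds = LayeredDataset(np.full((4, 24, 24), 120, np.uint8))
        part = slic(ds, target_size=64)
        fs = supervoxel_features(part)
        assert np.allclose(fs.data, fs.data[0])

    def test_single_region_neighbour_fallback(self):
        labels = np.zeros((1, 4, 4), np.int32)
        part = segauto.SupervoxelPartition(labels, 16, 0.05, 1)
        part.stats = segauto._region_stats(np.arange(16, dtype=float).reshape(1, 4, 4),
                                           labels, 1)
        part.adjacency = [set()]
        fs = supervoxel_features(part)
        own, nbr = fs.data[0, :12], fs.data[0, 12:]
        assert np.array_equal(own, nbr)

    def test_quantile_features_monotone(self, blob_phantom):
        ds, _ = blob_phantom
        part = slic(ds, target_size=100)
        fs = supervoxel_features(part)
        qcols = [fs.names.index(f"q{q}") for q in range(10, 100, 10)]
        qs = fs.data[:, qcols]
        assert (np.diff(qs, axis=1) >= 0).all()


class TestClassifiers:
    @staticmethod
    def _separable(n=300, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5)).astype(np.float32)
        y_true = X[:, 0] > 0
        lab = np.where(y_true, 1, 2).astype(np.uint8)
        if noise:
            flip = rng.random(n) < noise
            lab[flip] = 3 - lab[flip]
        return FeatureStack(X, "test-v1/f=5", [f"f{i}" for i in range(5)]), lab, y_true

    def test_separable_data_trains_to_100_percent(self):
        fs, lab, _ = self._separable()
        clf = train_classifier(fs, lab, "membrane", n_trees=30, seed=0)
        assert clf.training_accuracy == 1.0

    def test_same_seed_identical_predictions(self):
        fs, lab, _ = self._separable()
        a = train_classifier(fs, lab, "membrane", n_trees=30, seed=5)
        b = train_classifier(fs, lab, "membrane", n_trees=30, seed=5)
        assert np.array_equal(a.predict_proba(fs), b.predict_proba(fs))

    def test_label_noise_holdout_accuracy(self):
        fs_train, lab, _ = self._separable(400, seed=1, noise=0.10)
        fs_test, _, truth = self._separable(400, seed=2)
        clf = train_classifier(fs_train, lab, "membrane", n_trees=100, seed=0)
        pred = clf.predict_proba(fs_test) >= 0.5
        assert (pred == truth).mean() >= 0.90

    def test_membrane_phantom_recovery(self):
        assert scenarios.membrane_classifier_recovery(seed=5)["dice"] >= 0.8

    def test_network_phantom_recovery(self):
        assert scenarios.network_classifier_recovery(seed=0)["dice"] >= 0.9

    def test_probabilities_bounded(self):
        fs, lab, _ = self._separable()
        clf = train_classifier(fs, lab, "membrane", n_trees=20, seed=0)
        p = clf.predict_proba(fs)
        assert p.min() >= 0 and p.max() <= 1

    def test_supervoxel_prediction_constant_per_region(self, blob_phantom):
        ds, gt = blob_phantom
        part = slic(ds, target_size=40)
        seeds = SeedLabels.from_masks(gt.labels > 0, ndi.distance_transform_edt(
            gt.labels == 0) > 3)
        binary, clf = segauto.segment_with_supervoxel_classifier(part, seeds, seed=0)
        proba, _ = predict_classifier(clf, supervoxel_features(part), partition=part)
        for r in range(0, part.n_regions, 37):
            vals = proba[part.labels == r]
            assert np.ptp(vals) == 0

    def test_schema_mismatch_rejected_with_both_ids(self):
        fs, lab, _ = self._separable()
        clf = train_classifier(fs, lab, "membrane", n_trees=10, seed=0)
        other = FeatureStack(fs.data, "other-v2/f=5", fs.names)
        with pytest.raises(ValueError, match="test-v1.*other-v2"):
            clf.predict_proba(other)

    def test_too_few_samples_rejected(self):
        fs, lab, _ = self._separable(n=12)
        lab[:] = 2
        lab[:3] = 1
        with pytest.raises(ValueError, match=">= 10"):
            train_classifier(fs, lab, "membrane")

    def test_single_class_rejected(self):
        fs, lab, _ = self._separable()
        lab[:] = 1
        with pytest.raises(ValueError, match="both"):
            train_classifier(fs, lab, "membrane")

    def test_persistence_round_trip(self, tmp_path):
        fs, lab, _ = self._separable()
        clf = train_classifier(fs, lab, "supervoxel", n_trees=15, seed=3)
        clf.save(tmp_path / "clf.joblib")
        back = TrainedClassifier.load(tmp_path / "clf.joblib")
        assert back.schema_id == clf.schema_id
        assert back.seed == clf.seed
        assert np.array_equal(back.predict_proba(fs), clf.predict_proba(fs))
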