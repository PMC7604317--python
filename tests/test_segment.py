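"""Segmentation and morphometry against phantom ground truth."""

import numpy as np
import pytest

from ovamap.rubric import classify_follicle
from ovamap.segment import (FeatureParams, FollicleFeatures,
                            SegmentationParams, extract_features,
                            match_labels, measure_diameter, segment_follicles,
                            segment_organ)
from ovamap.volio import VoxelVolume


def voxel_sphere(radius_vox: int) -> np.ndarray:
    n = 2 * radius_vox + 7
    c = (n - 1) / 2
    ax = np.arange(n) - c
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius_vox**2


class TestMeasureDiameter:
    def test_feret_of_t8_calibration_sphere(self):
        # a sphere of radius 107 voxels at 1.5 um/voxel spans the printed
        # fully-grown follicle diameter
        d = measure_diameter(voxel_sphere(107), 1.5, "max_feret")
        assert d == pytest.approx(321.0, abs=1.5)

    def test_feret_of_small_spheres_exact(self):
        for r in (5, 12, 30):
            d = measure_diameter(voxel_sphere(r), 2.0, "max_feret")
            assert d == pytest.approx(2 * r * 2.0, abs=2.0)

    def test_cylinder_cross_section(self):
        yy, xx = np.meshgrid(np.arange(105) - 52, np.arange(105) - 52,
                             indexing="ij")
        disk = (yy**2 + xx**2) <= 50**2
        cyl = np.broadcast_to(disk, (300, 105, 105)).copy()
        d = measure_diameter(cyl, 1.5, "cross_section")
        assert d == pytest.approx(150.0, abs=1.5)

    def test_single_voxel_is_one_voxel(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        assert measure_diameter(one, 1.5, "max_feret") == 1.5

    def test_empty_region_errors(self):
        with pytest.raises(ValueError, match="empty"):
            measure_diameter(np.zeros((3, 3, 3), bool), 1.5)

    def test_flat_region_degenerate(self):
        flat = np.zeros((1, 9, 9), dtype=bool)
        flat[0, 4, :] = True
        assert measure_diameter(flat, 1.0, "max_feret") == pytest.approx(8.0)


class TestSegmentOrgan:
    def test_dice_vs_ground_truth(self, feature_phantom):
        _, vol, gt = feature_phantom  # noise_sd = 5
        mask = segment_organ(vol)
        inter = (mask & gt.organ_mask).sum()
        dice = 2 * inter / (mask.sum() + gt.organ_mask.sum())
        assert dice >= 0.98

    def test_single_connected_component(self, feature_phantom):
        from scipy import ndimage
        _, vol, _ = feature_phantom
        _, n = ndimage.label(segment_organ(vol))
        assert n == 1

    def test_constant_volume_errors(self):
        with pytest.raises(ValueError, match="constant|empty"):
            segment_organ(VoxelVolume(np.zeros((8, 8, 8), np.uint8), 1.5))


class TestSegmentFollicles:
    def test_perfect_recall_on_clean_phantom(self, seg_phantom):
        spec, vol, gt = seg_phantom
        organ = segment_organ(vol)
        labels, cands = segment_follicles(vol, organ)
        m = match_labels(labels, gt.label_volume)
        assert m["recall"] == 1.0
        assert m["precision"] >= 0.95

    def test_diameter_error_below_two_voxels(self, seg_phantom):
        spec, vol, gt = seg_phantom
        organ = segment_organ(vol)
        labels, _ = segment_follicles(vol, organ)
        m = match_labels(labels, gt.label_volume)
        for f in gt.follicles:
            pred = m["matches"][f.id]
            d = measure_diameter(labels == pred, spec.voxel_size)
            assert abs(d - f.diameter) <= 2 * spec.voxel_size

    def test_labels_partition_within_organ(self, seg_phantom):
        _, vol, _ = seg_phantom
        organ = segment_organ(vol)
        labels, _ = segment_follicles(vol, organ)
        assert not (labels[~organ] > 0).any()

    def test_empty_interior_gives_zero_candidates(self):
        data = np.zeros((40, 40, 40), np.uint8)
        data[5:35, 5:35, 5:35] = 110  # organ tissue, nothing brighter
        vol = VoxelVolume(data, 2.0)
        organ = data > 0
        labels, cands = segment_follicles(
            vol, organ, SegmentationParams(threshold=150.0))
        assert cands == []
        assert labels.max() == 0

    def test_watershed_splits_touching_spheres(self):
        # two bright solid spheres bridged by a 1-voxel shell contact
        data = np.full((40, 72, 40), 110, np.uint8)
        zz, yy, xx = np.ogrid[:40, :72, :40]
        s1 = (zz - 20) ** 2 + (yy - 22) ** 2 + (xx - 20) ** 2 <= 14**2
        s2 = (zz - 20) ** 2 + (yy - 51) ** 2 + (xx - 20) ** 2 <= 14**2
        data[s1 | s2] = 190
        vol = VoxelVolume(data, 2.0)
        organ = np.ones_like(s1)
        labels, cands = segment_follicles(
            vol, organ, SegmentationParams(threshold=150.0))
        follicle_ids = {c.label for c in cands if not c.is_vessel}
        assert len(follicle_ids) == 2

    def test_elongated_object_routed_to_vessels(self):
        data = np.full((30, 30, 120), 110, np.uint8)
        data[12:18, 12:18, 5:115] = 190  # a bright tube
        vol = VoxelVolume(data, 2.0)
        labels, cands = segment_follicles(
            vol, np.ones(data.shape, bool),
            SegmentationParams(threshold=150.0, min_diameter=10.0))
        assert len(cands) == 1
        assert cands[0].is_vessel


@pytest.fixture(scope="session")
def truth_features(feature_phantom):
    _, vol, gt = feature_phantom
    out = {}
    for f in gt.follicles:
        out[f.id] = (f, extract_features(
            vol, gt.label_volume == f.id, organ_mask=gt.organ_mask))
    return out


class TestExtractFeatures:
    def test_morphology_flags_reproduced(self, truth_features):
        for f, feats in truth_features.values():
            assert feats.zp_present == f.has_zp, f.stage
            assert feats.n_antra == f.n_antra, f.stage

    def test_t8_antrum_fraction(self, truth_features):
        for f, feats in truth_features.values():
            if f.stage == "T8":
                assert feats.n_antra == 1
                assert feats.antrum_fraction >= 0.3
                assert feats.zp_present

    def test_t4_darker_than_t5(self, truth_features):
        t4 = [feats.mean_radiopacity for f, feats in truth_features.values()
              if f.stage == "T4"]
        t5 = [feats.mean_radiopacity for f, feats in truth_features.values()
              if f.stage == "T5"]
        assert max(t4) < min(t5)
        for f, feats in truth_features.values():
            if f.stage == "T4":
                assert not feats.zp_present

    def test_staging_from_truth_regions_is_exact(self, truth_features):
        for f, feats in truth_features.values():
            stage, _ = classify_follicle(feats)
            assert stage == f.stage

    def test_measured_diameter_close_to_truth(self, truth_features):
        for f, feats in truth_features.values():
            assert abs(feats.major_diameter - f.diameter) <= 2 * 2.0

    def test_feature_invariants(self):
        with pytest.raises(ValueError):
            FollicleFeatures(major_diameter=0.0, n_antra=0,
                             antrum_fraction=0.0, zp_present=False,
                             oocyte_present=False, mean_radiopacity=0.5,
                             volume_voxels=10)
        with pytest.raises(ValueError):
            FollicleFeatures(major_diameter=50.0, n_antra=0,
                             antrum_fraction=0.2, zp_present=False,
                             oocyte_present=False, mean_radiopacity=0.5,
                             volume_voxels=10)
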