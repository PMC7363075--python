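"""Lesion labeling, border extraction, patch sampling and dataset build."""
import numpy as np
import pytest
from scipy import ndimage

from strokect.ctio import NormalizedVolume, SegmentationMask
from strokect.errors import ConfigError, DataError, ParameterError
from strokect.patchnet import (DualResolutionPatch, PatchClassifierConfig,
                               build_patch_dataset, extract_dual_patch,
                               label_lesions, lesion_border,
                               sample_border_positions)


def _vol(voxels, spacing=(5.0, 2.0, 2.0)):
    return NormalizedVolume(np.asarray(voxels, np.float32), spacing)


class TestLabelLesions:
    def test_two_blobs_two_lesions(self):
        m = np.zeros((4, 10, 10), np.uint8)
        m[0, 1:3, 1:3] = 1
        m[3, 7:9, 7:9] = 1
        lesions = label_lesions(SegmentationMask(m, (5, 2, 2)))
        assert len(lesions) == 2
        assert sum(len(l.coords) for l in lesions) == 8

    def test_diagonal_voxels_single_lesion_under_26_connectivity(self):
        m = np.zeros((1, 4, 4), np.uint8)
        m[0, 1, 1] = 1
        m[0, 2, 2] = 1  # touches only diagonally in-plane
        lesions = label_lesions(SegmentationMask(m, (5, 2, 2)))
        assert len(lesions) == 1

    def test_empty_mask_empty_list(self):
        assert label_lesions(SegmentationMask(np.zeros((2, 4, 4), np.uint8),
                                              (5, 2, 2))) == []

    def test_volume_from_spacing(self):
        m = np.zeros((2, 4, 4), np.uint8)
        m[0, 0:2, 0:2] = 1  # 4 voxels of 5x2x2 mm = 80 mm^3
        (lesion,) = label_lesions(SegmentationMask(m, (5.0, 2.0, 2.0)))
        assert lesion.volume_cm3 == pytest.approx(0.08)


class TestLesionBorder:
    def test_filled_square_perimeter(self):
        m = np.zeros((1, 9, 9), np.uint8)
        m[0, 2:7, 2:7] = 1  # 5x5 square
        border = lesion_border(SegmentationMask(m, (5, 2, 2)))
        assert len(border.points) == 16

    def test_single_voxel_is_its_own_border(self):
        m = np.zeros((1, 5, 5), np.uint8)
        m[0, 2, 2] = 1
        border = lesion_border(SegmentationMask(m, (5, 2, 2)))
        np.testing.assert_array_equal(border.points, [[0, 2, 2]])

    def test_border_subset_of_lesion(self, stroke_phantom):
        border = lesion_border(stroke_phantom.lesions)
        les = stroke_phantom.lesions.voxels.astype(bool)
        assert all(les[tuple(p)] for p in border.points)

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            lesion_border(SegmentationMask(np.zeros((1, 4, 4), np.uint8),
                                           (5, 2, 2)))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_inplane_adjacency_oracle(self, seed):
        # border == lesion voxels with a non-lesion pixel in their in-plane
        # 3x3 neighbourhood, checked by brute force on random masks
        r = np.random.default_rng(seed)
        m = (ndimage.gaussian_filter(r.random((3, 12, 12)), 1.2) > 0.55)
        if not m.any():
            return
        border = lesion_border(SegmentationMask(m.astype(np.uint8), (5, 2, 2)))
        got = set(map(tuple, border.points))
        expected = set()
        for z, y, x in np.argwhere(m):
            nb = m[z, max(0, y - 1):y + 2, max(0, x - 1):x + 2]
            on_edge = (y in (0, m.shape[1] - 1)) or (x in (0, m.shape[2] - 1))
            if (~nb).any() or on_edge:
                expected.add((z, y, x))
        assert got == expected


class TestSampleBorderPositions:
    def _border(self, n):
        pts = np.stack([np.zeros(n, int), np.arange(n), np.arange(n)], axis=1)
        from strokect.patchnet import BorderPointSet

        return BorderPointSet(lesion_id=0, points=pts)

    def test_large_border_distinct_positions(self):
        picked = sample_border_positions(self._border(200), n=70, seed=0)
        assert len(picked) == 70
        assert len({tuple(p) for p in picked}) == 70  # without replacement

    def test_small_border_with_replacement(self):
        picked = sample_border_positions(self._border(5), n=70, seed=0)
        assert len(picked) == 70
        assert {tuple(p) for p in picked} <= {(0, i, i) for i in range(5)}

    def test_seeded_repeat_identical(self):
        a = sample_border_positions(self._border(100), n=70, seed=4)
        b = sample_border_positions(self._border(100), n=70, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_empty_border_rejected(self):
        from strokect.patchnet import BorderPointSet

        with pytest.raises(ParameterError):
            sample_border_positions(BorderPointSet(0, np.empty((0, 3))), n=70)


class TestExtractDualPatch:
    def test_constant_volume_constant_patches(self):
        vol = _vol(np.full((10, 80, 80), 0.5))
        p = extract_dual_patch(vol, (5, 40, 40))
        assert p.fine.shape == (3, 32, 32)
        assert p.coarse.shape == (3, 32, 32)
        np.testing.assert_allclose(p.fine, 0.5)
        np.testing.assert_allclose(p.coarse, 0.5)

    def test_fine_center_matches_volume_value(self, rng):
        v = rng.random((10, 80, 80)).astype(np.float32)
        vol = _vol(v)
        p = extract_dual_patch(vol, (5, 40, 37))
        assert p.fine[1, 16, 16] == pytest.approx(v[5, 40, 37])

    def test_corner_center_zero_padded(self, rng):
        v = rng.random((6, 40, 40)).astype(np.float32) * 0.5 + 0.25
        p = extract_dual_patch(_vol(v), (0, 0, 0))
        assert p.fine.shape == (3, 32, 32)
        assert np.all(p.fine[0] == 0.0)          # slice z=-1 padded
        assert np.all(p.fine[1, :16, :] == 0.0)  # rows y<0 padded
        assert np.all(p.fine[1, :, :16] == 0.0)  # cols x<0 padded
        assert p.fine[1, 16, 16] == pytest.approx(v[0, 0, 0])

    def test_center_outside_volume_rejected(self):
        with pytest.raises(ParameterError):
            extract_dual_patch(_vol(np.zeros((4, 8, 8))), (4, 0, 0))

    def test_translation_consistency(self, rng):
        v = rng.random((12, 90, 90)).astype(np.float32)
        shifted = np.roll(v, shift=(0, 3, -2), axis=(0, 1, 2))
        a = extract_dual_patch(_vol(v), (6, 45, 45))
        b = extract_dual_patch(_vol(shifted), (6, 48, 43))
        np.testing.assert_allclose(a.fine, b.fine, atol=1e-6)
        np.testing.assert_allclose(a.coarse, b.coarse, atol=1e-6)

    def test_coarse_is_average_pooled_wide_window(self, rng):
        v = rng.random((8, 80, 80)).astype(np.float32)
        p = extract_dual_patch(_vol(v), (4, 40, 40))
        wide = v[3:6, 40 - 32:40 + 32, 40 - 32:40 + 32]
        expected = wide.reshape(3, 32, 2, 32, 2).mean(axis=(2, 4))
        np.testing.assert_allclose(p.coarse, expected, atol=1e-6)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ParameterError):
            DualResolutionPatch(fine=np.zeros((3, 16, 16)),
                                coarse=np.zeros((3, 32, 32)), center=(0, 0, 0))


class TestBuildPatchDataset:
    def _patches(self, n, label):
        return [DualResolutionPatch(fine=np.full((3, 32, 32), i / max(n, 1),
                                                 np.float32),
                                    coarse=np.zeros((3, 32, 32), np.float32),
                                    center=(0, 0, 0), label=label)
                for i in range(n)]

    def test_minority_oversampled_to_parity(self):
        patches, labels = build_patch_dataset(self._patches(40, "stroke"),
                                              self._patches(100, "non-stroke"),
                                              seed=0)
        assert len(patches) == 200
        assert (labels == 1).sum() == 100
        assert (labels == 0).sum() == 100

    def test_balanced_input_unchanged_in_size(self):
        patches, labels = build_patch_dataset(self._patches(30, "stroke"),
                                              self._patches(30, "non-stroke"),
                                              seed=0)
        assert len(patches) == 60
        assert (labels == 1).sum() == 30

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            build_patch_dataset([], self._patches(5, "non-stroke"))


class TestPatchClassifierConfig:
    def test_published_defaults(self):
        cfg = PatchClassifierConfig()
        assert cfg.dropout == 0.2
        assert cfg.learning_rate == 1e-5
        assert cfg.epochs == 5
        assert cfg.bn_momentum == 0.99
        assert cfg.bn_eps == 1e-3

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ConfigError):
            PatchClassifierConfig(dropout=1.0)

    def test_invalid_block_spec_rejected(self):
        with pytest.raises(ConfigError):
            PatchClassifierConfig(blocks=0)


class TestPatchDatasetCache:
    def test_round_trip(self, tmp_path, rng):
        patches = [DualResolutionPatch(
            fine=rng.random((3, 32, 32)).astype(np.float32),
            coarse=rng.random((3, 32, 32)).astype(np.float32),
            center=(1, 2 + i, 3), label="stroke" if i % 2 else "non-stroke")
            for i in range(4)]
        labels = np.array([0, 1, 0, 1])
        from strokect.patchnet import load_patch_dataset, save_patch_dataset

        save_patch_dataset(patches, labels, tmp_path / "cache")
        loaded, lab = load_patch_dataset(tmp_path / "cache")
        np.testing.assert_array_equal(lab, labels)
        assert [p.center for p in loaded] == [p.center for p in patches]
        assert [p.label for p in loaded] == [p.label for p in patches]
        for a, b in zip(loaded, patches):
            np.testing.assert_allclose(a.fine, b.fine)
            np.testing.assert_allclose(a.coarse, b.coarse)
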