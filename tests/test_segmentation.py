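import numpy as np
import pytest
from _oracles import bfs_components, median_brute, otsu_exhaustive

from spikect import (
    BinaryMask,
    SegmentationParams,
    Volume,
    binarize,
    label_components,
    median_filter_3d,
    otsu_threshold,
    remove_small_grains,
    segment_grains,
    watershed_split,
)
from spikect.volume_io import LabelMap


def _volume_from_histogram(values, counts):
    arr = np.repeat(np.asarray(values, np.uint16), counts)
    return arr.reshape(1, 1, -1)


class TestOtsu:
    def test_two_level_equal_counts_gives_smallest_tie(self):
        arr = np.array([[[0, 0, 100, 100]]], np.uint16)
        assert otsu_threshold(Volume(arr, 77)) == 0

    def test_small_histogram_matches_exhaustive_search(self):
        values, counts = [0, 3, 4], [4, 2, 2]
        vol = Volume(_volume_from_histogram(values, counts), 77)
        assert otsu_threshold(vol) == otsu_exhaustive(values, counts)

    def test_random_histograms_match_exact_rational_oracle(self, rng):
        for _ in range(60):
            n_vals = int(rng.integers(2, 12))
            values = sorted(rng.choice(64, size=n_vals, replace=False).tolist())
            counts = rng.integers(1, 20, size=n_vals).tolist()
            vol = Volume(_volume_from_histogram(values, counts), 77)
            assert otsu_threshold(vol) == otsu_exhaustive(values, counts)

    def test_bimodal_gaussian_modes_straddle_threshold(self, rng):
        lo = rng.normal(500, 100, 4000).clip(0, 65535)
        hi = rng.normal(5000, 100, 4000).clip(0, 65535)
        arr = np.concatenate([lo, hi]).round().astype(np.uint16).reshape(2, 40, 100)
        t = otsu_threshold(Volume(arr, 77))
        assert lo.mean() <= t < hi.mean()

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(Volume(np.full((2, 2, 2), 7, np.uint16), 77))


class TestBinarize:
    def test_threshold_extremes(self):
        vol = Volume(np.arange(8, dtype=np.uint16).reshape(2, 2, 2) + 1, 77)
        assert binarize(vol, 0).values.all()
        assert not binarize(vol, 8).values.any()

    def test_count_matches_per_voxel_scan(self, rng):
        arr = rng.integers(0, 100, size=(4, 5, 6)).astype(np.uint16)
        t = 37
        mask = binarize(Volume(arr, 77), t)
        assert mask.values.sum() == sum(
            1 for v in arr.ravel() if v > t
        )


class TestMedianFilter:
    def test_constant_mask_unchanged(self):
        mask = BinaryMask(np.ones((4, 4, 4), np.uint8), 77)
        np.testing.assert_array_equal(median_filter_3d(mask, 3).values, 1)

    def test_isolated_voxel_removed(self):
        arr = np.zeros((5, 5, 5), np.uint8)
        arr[2, 2, 2] = 1
        out = median_filter_3d(BinaryMask(arr, 77), 3)
        assert out.values.sum() == 0

    def test_matches_sort_and_take_middle_oracle(self, rng):
        arr = (rng.random((7, 7, 7)) < 0.5).astype(np.uint8)
        out = median_filter_3d(BinaryMask(arr, 77), 3)
        np.testing.assert_array_equal(out.values, median_brute(arr, 3))

    @pytest.mark.parametrize("size", [1, 5])
    def test_other_sizes_match_oracle(self, rng, size):
        arr = (rng.random((6, 5, 7)) < 0.4).astype(np.uint8)
        out = median_filter_3d(BinaryMask(arr, 77), size)
        np.testing.assert_array_equal(out.values, median_brute(arr, size))

    def test_monotone_in_foreground(self, rng):
        base = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        extra = base | (rng.random((6, 6, 6)) < 0.2)
        out_base = median_filter_3d(BinaryMask(base, 77), 3).values
        out_extra = median_filter_3d(BinaryMask(extra.astype(np.uint8), 77), 3).values
        assert np.all(out_extra >= out_base)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            median_filter_3d(BinaryMask(np.zeros((3, 3, 3), np.uint8), 77), 4)


class TestLabelComponents:
    def test_empty_mask(self):
        out = label_components(BinaryMask(np.zeros((3, 3, 3), np.uint8), 77))
        assert out.n_labels == 0

    def test_two_disjoint_cubes(self):
        arr = np.zeros((9, 9, 9), np.uint8)
        arr[0:3, 0:3, 0:3] = 1
        arr[6:9, 6:9, 6:9] = 1
        out = label_components(BinaryMask(arr, 77), 26)
        assert out.n_labels == 2
        assert (out.labels == 1).sum() == 27
        assert (out.labels == 2).sum() == 27

    def test_corner_contact_depends_on_connectivity(self):
        arr = np.zeros((4, 4, 4), np.uint8)
        arr[1, 1, 1] = 1
        arr[2, 2, 2] = 1
        assert label_components(BinaryMask(arr, 77), 26).n_labels == 1
        assert label_components(BinaryMask(arr, 77), 6).n_labels == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_flood_fill(self, rng, connectivity):
        for _ in range(8):
            arr = (rng.random((7, 8, 9)) < 0.35).astype(np.uint8)
            out = label_components(BinaryMask(arr, 77), connectivity)
            oracle = bfs_components(arr, connectivity)
            assert out.n_labels == len(oracle)
            got = {
                frozenset(map(tuple, np.argwhere(out.labels == k)))
                for k in range(1, out.n_labels + 1)
            }
            assert got == set(oracle)

    def test_ids_ordered_by_lexicographic_min_voxel(self):
        arr = np.zeros((5, 5, 5), np.uint8)
        arr[3, 0, 0] = 1  # later z: must get the higher id
        arr[0, 4, 4] = 1
        out = label_components(BinaryMask(arr, 77), 26)
        assert out.labels[0, 4, 4] == 1
        assert out.labels[3, 0, 0] == 2


def _sphere_mask(shape, centre, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
        <= radius**2
    )


class TestWatershedSplit:
    def test_single_sphere_single_label(self):
        mask = _sphere_mask((16, 16, 16), (8, 8, 8), 6).astype(np.uint8)
        out = watershed_split(BinaryMask(mask, 77))
        assert out.n_labels == 1
        np.testing.assert_array_equal(out.labels > 0, mask.astype(bool))

    def test_two_overlapping_spheres_split_with_accurate_centroids(self):
        shape = (16, 16, 26)
        a, b = (8, 8, 8), (8, 8, 17)  # centres 9 voxels apart, radius 6
        mask = (_sphere_mask(shape, a, 6) | _sphere_mask(shape, b, 6)).astype(np.uint8)
        out = watershed_split(BinaryMask(mask, 77))
        assert out.n_labels == 2
        for k in (1, 2):
            centroid = np.argwhere(out.labels == k).mean(axis=0)
            nearest = min(
                np.linalg.norm(centroid - np.array(c)) for c in (a, b)
            )
            assert nearest < 1.5

    def test_labels_partition_foreground_exactly(self, rng):
        arr = np.zeros((14, 14, 14), np.uint8)
        for _ in range(4):
            c = rng.integers(3, 11, size=3)
            arr |= _sphere_mask(arr.shape, c, int(rng.integers(2, 4))).astype(np.uint8)
        out = watershed_split(BinaryMask(arr, 77))
        np.testing.assert_array_equal(out.labels > 0, arr.astype(bool))
        # exactly one label per voxel is implied by the single label array;
        # also check every label id is used
        ids = np.unique(out.labels)
        assert set(ids.tolist()) == set(range(out.n_labels + 1))

    def test_empty_mask_gives_empty_labelmap(self):
        out = watershed_split(BinaryMask(np.zeros((4, 4, 4), np.uint8), 77))
        assert out.n_labels == 0


class TestRemoveSmallGrains:
    def test_zero_threshold_is_identity(self, rng):
        arr = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        lab = label_components(BinaryMask(arr, 77))
        out = remove_small_grains(lab, 0.0)
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_tiny_blob_removed_by_forced_arithmetic(self):
        arr = np.zeros((5, 5, 5), np.int32)
        arr[1, 1, :2] = 1  # 2 voxels; at 77 um that is ~9e-4 mm^3
        out = remove_small_grains(LabelMap(arr, 77), 5.0)
        assert out.n_labels == 0

    def test_surviving_set_matches_brute_force_filter(self, rng):
        arr = np.zeros((10, 10, 10), np.uint8)
        arr[0:2, 0:2, 0:2] = 1  # 8 voxels
        arr[5:9, 5:9, 5:9] = 1  # 64 voxels
        lab = label_components(BinaryMask(arr, 1000.0), 26)  # 1 mm voxels
        threshold = 0.01  # keeps both at 1 mm voxels
        out = remove_small_grains(lab, 10.0)  # 10 mm^3: drops the 8-voxel blob
        voxvol = 1.0
        survivors = [
            k
            for k in range(1, lab.n_labels + 1)
            if (lab.labels == k).sum() * voxvol >= 10.0
        ]
        assert out.n_labels == len(survivors)
        assert (out.labels > 0).sum() == sum(
            (lab.labels == k).sum() for k in survivors
        )
        del threshold


class TestSegmentGrains:
    def test_noise_free_phantom_recovers_exact_grain_count(self, small_phantom):
        vol, truth = small_phantom
        lab = segment_grains(vol)
        assert lab.n_labels == truth.n_grains

    def test_noisy_touching_phantom_counts_and_volumes(self, noisy_touching_phantom):
        vol, truth = noisy_touching_phantom
        lab = segment_grains(vol)
        assert lab.n_labels == truth.n_grains
        counts = np.bincount(lab.labels.ravel())[1:]
        true_counts = np.sort(truth.grains["voxel_count"].to_numpy())
        rel = np.abs(np.sort(counts) - true_counts) / true_counts
        assert rel.max() < 0.10

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError):
            segment_grains(Volume(np.zeros((4, 4, 4), np.uint16), 77))

    def test_deterministic(self, small_phantom):
        vol, _ = small_phantom
        a = segment_grains(vol, SegmentationParams())
        b = segment_grains(vol, SegmentationParams())
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSegmentationParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"median_size": 2},
            {"connectivity": 18},
            {"min_grain_volume_mm3": -1},
            {"watershed_h": -0.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)
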