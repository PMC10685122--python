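"""Dense flow, sigma_px accumulation, inactive-ant classification and the
mask / ring / random-pixel comparisons."""

import numpy as np
import pytest

from antsync.optical_flow_analysis import (
    accumulate_sigma,
    adjacency_paired_test,
    adjacent_ring,
    brood_pile_metrics,
    classify_inactive,
    coverage_proportion,
    dense_flow,
    inactive_vs_random,
)


def blob_frames(shifts, shape=(100, 150), cy=50, cx0=40):
    """Grayscale frames of one elliptical blob translated by given x offsets."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    frames = []
    for s in shifts:
        img = np.full(shape, 200.0)
        img[((yy - cy) / 8.0) ** 2 + ((xx - cx0 - s) / 15.0) ** 2 <= 1] = 60.0
        frames.append(img)
    return np.stack(frames)


class TestDenseFlow:
    def test_static_scene_all_zero(self):
        frames = blob_frames([0, 0, 0])
        assert not dense_flow(frames).magnitudes.any()

    def test_translation_magnitude_on_blob(self):
        frames = blob_frames([0, 3])
        mag = dense_flow(frames).magnitudes[0]
        yy, xx = np.mgrid[:100, :150]
        on_blob = ((yy - 50) / 8.0) ** 2 + ((xx - 40) / 15.0) ** 2 <= 1
        assert np.median(mag[on_blob]) == pytest.approx(3.0, abs=1.0)
        # outside the blob's flow halo (window radius + displacement) all zero
        off = ~np.asarray(
            ((yy - 50) / 18.0) ** 2 + ((xx - 41.5) / 28.0) ** 2 <= 1
        )
        assert mag[off].max() == 0.0

    def test_subthreshold_motion_floored(self):
        """A 1 px/frame translation sits below the 1.5 px/frame noise floor."""
        frames = blob_frames([0, 1])
        assert not dense_flow(frames).magnitudes.any()

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            dense_flow([np.zeros((10, 10)), np.zeros((12, 10))])


class TestSigmaPx:
    def test_single_pair_identity(self):
        frames = blob_frames([0, 3])
        field = dense_flow(frames)
        assert np.array_equal(accumulate_sigma(field).sigma, field.magnitudes[0])

    def test_additive_over_concatenated_clips(self):
        frames = blob_frames([0, 3, 6, 9, 12])
        whole = accumulate_sigma(dense_flow(frames)).sigma
        first = accumulate_sigma(dense_flow(frames[:3])).sigma
        second = accumulate_sigma(dense_flow(frames[2:])).sigma
        assert np.allclose(whole, first + second)

    def test_path_pixels_accumulate(self):
        frames = blob_frames(np.arange(0, 30, 3))
        sigma = accumulate_sigma(dense_flow(frames)).sigma
        assert sigma[50, 55] > 3.0  # swept by the blob over several pairs
        assert sigma[10, 10] == 0.0


class TestClassifyInactive:
    def test_persistent_blob_retained(self):
        m = np.zeros((30, 30), bool)
        m[5:15, 5:15] = True
        stack = np.repeat(m[None], 10, axis=0)
        assert np.array_equal(classify_inactive(stack, min_component=10).mask, m)

    def test_eighty_percent_presence_removed(self):
        """A blob present in 8 of 10 frames fails the 90% persistence rule."""
        m = np.zeros((30, 30), bool)
        m[5:15, 5:15] = True
        stack = np.repeat(m[None], 10, axis=0)
        stack[0] = stack[1] = False
        assert not classify_inactive(stack, min_component=10).mask.any()

    def test_small_speckle_removed(self):
        m = np.zeros((40, 40), bool)
        m[3:8, 3:7] = True  # 20-px speckle
        stack = np.repeat(m[None], 5, axis=0)
        assert not classify_inactive(stack, min_component=62).mask.any()
        assert classify_inactive(stack, min_component=20).mask.sum() == 20

    def test_monotone_in_persistence(self, rng):
        stack = rng.random((10, 25, 25)) < 0.7
        prev = None
        for p in [0.5, 0.7, 0.9, 1.0]:
            mask = classify_inactive(stack, persistence=p, min_component=1).mask
            if prev is not None:
                assert not (mask & ~prev).any()  # raising never adds pixels
            prev = mask

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            classify_inactive(np.zeros((0, 5, 5), bool))


class TestInactiveVsRandom:
    def test_all_zero_sigma_degenerate(self):
        mask = np.zeros((20, 20), bool)
        mask[4:10, 4:14] = True
        rep = inactive_vs_random(np.zeros((20, 20)), mask, rng=0)
        assert rep.degenerate and np.isnan(rep.pvalue)
        assert rep.median_inactive == rep.median_random == 0.0

    def test_whole_frame_mask_is_null(self, rng):
        sigma = rng.random((30, 30))
        rep = inactive_vs_random(sigma, np.ones((30, 30), bool), rng=1)
        assert rep.pvalue > 1e-4  # both samples from the same population
        assert len(rep.random_values) == len(rep.inactive_values) == 900

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inactive_vs_random(np.zeros((5, 5)), np.ones((6, 6), bool))


def brute_force_dilation(mask, k):
    """Oracle: shift-and-OR dilation with a k x k square structuring element."""
    out = np.zeros_like(mask)
    H, W = mask.shape
    offs = range(-(k // 2), k - k // 2)
    for dy in offs:
        for dx in offs:
            src = mask[
                max(0, -dy) : H - max(0, dy), max(0, -dx) : W - max(0, dx)
            ]
            out[max(0, dy) : H - max(0, -dy), max(0, dx) : W - max(0, -dx)] |= src
    return out


class TestAdjacentRing:
    def test_empty_mask(self):
        assert not adjacent_ring(np.zeros((20, 20), bool)).any()

    def test_square_matches_brute_force_dilation(self):
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        ring = adjacent_ring(mask, thickness=10)
        expected = brute_force_dilation(mask, 10) & ~mask
        assert np.array_equal(ring, expected)
        assert ring.sum() == expected.sum()

    def test_random_masks_match_oracle_and_stay_disjoint(self, rng):
        for _ in range(10):
            mask = rng.random((30, 30)) < 0.15
            ring = adjacent_ring(mask, thickness=10)
            assert not (ring & mask).any()
            assert np.array_equal(ring, brute_force_dilation(mask, 10) & ~mask)

    def test_overlapping_rings_merge_without_double_count(self):
        mask = np.zeros((40, 60), bool)
        mask[18:22, 10:14] = True
        mask[18:22, 20:24] = True  # rings of the two blobs overlap
        ring = adjacent_ring(mask, thickness=10)
        assert ring.dtype == bool and not (ring & mask).any()


class TestAdjacencyPairedTest:
    def test_consistent_dominance_significant(self):
        mask_sums = np.array([1.0, 2, 3, 4, 5, 6])
        rep = adjacency_paired_test(mask_sums, mask_sums + 10)
        assert rep.pvalue < 0.05

    def test_identical_pairs_no_difference(self):
        rep = adjacency_paired_test(np.ones(6), np.ones(6))
        assert rep.no_difference and rep.pvalue == 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            adjacency_paired_test(np.ones(4), np.ones(4))


class TestBroodPileMetrics:
    def test_wrong_crop_size_named_error(self):
        with pytest.raises(ValueError, match="100x150"):
            brood_pile_metrics(np.zeros((30, 90, 90)))

    def test_coverage_counting_exact(self):
        """Flow in exactly 30 of the 150 regions -> coverage 0.2."""
        mags = np.zeros((1, 100, 150))
        for k in range(30):  # one pixel inside each of 30 distinct regions
            row, col = divmod(k, 15)
            mags[0, row * 10 + 4, col * 10 + 4] = 2.0
        assert coverage_proportion(mags) == pytest.approx(0.2)

    def test_no_flow_no_coverage(self, brood_scene):
        static = np.repeat(brood_scene.frames[:1], 30, axis=0)
        df = brood_pile_metrics(
            static, per_ant_area=brood_scene.per_ant_area, min_component=20
        )
        assert (df.coverage == 0).all()
        assert (df.mask_flow_sum == 0).all() and (df.ring_flow_sum == 0).all()

    def test_detouring_scene_ring_dominates(self, brood_scene):
        """Movers skirt the resting cluster, so flow lands beside, not on,
        inactive ants: sigma_px on the mask stays 0 while the ring collects."""
        df = brood_pile_metrics(
            brood_scene.frames,
            per_ant_area=brood_scene.per_ant_area,
            min_component=20,
        )
        assert (df.ring_flow_sum > df.mask_flow_sum).all()
        assert df.inactive_count.iloc[0] == pytest.approx(8, abs=1.5)
        sigma = accumulate_sigma(dense_flow(brood_scene.frames.astype(float)))
        assert sigma.sigma[brood_scene.resting_mask].max() == 0.0
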