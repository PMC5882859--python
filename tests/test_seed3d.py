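import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivmhisto.preprocess import BinaryMask
from ivmhisto.seed3d import (
    DetectionParams,
    SeedSet,
    StepGating,
    TUKEY_FENCE_FACTOR,
    background_mode,
    count_cells,
    detect_seeds,
    local_maxima_3d,
    mean_filter_3d,
    read_seeds,
    step_gate_cutoff,
    surround_mean,
    tukey_threshold,
    write_seeds,
)
from ivmhisto.stacks_io import ImageStack
from ivmhisto.synth import SynthParams, generate_cell_stack

from tests.conftest import SPARSE_DETECTION


def _stack(arr, dtype=np.uint8):
    return ImageStack(np.asarray(arr, dtype=dtype), (1.0, 1.0, 1.0))


class TestMeanFilter:
    def test_constant_stack_unchanged(self):
        out = mean_filter_3d(_stack(np.full((5, 5, 5), 40)))
        np.testing.assert_allclose(out.voxels, 40.0)

    def test_single_voxel_spreads_over_27_neighbours(self):
        arr = np.zeros((7, 7, 7))
        arr[3, 3, 3] = 27
        out = mean_filter_3d(_stack(arr), kernel=1)
        assert (out.voxels == 1).sum() == 27
        assert out.voxels.sum() == pytest.approx(27)

    def test_kernel_zero_rejected(self):
        with pytest.raises(ValueError, match="kernel must be >= 1"):
            mean_filter_3d(_stack(np.zeros((2, 2, 2))), kernel=0)


def _gaussian_blob(shape, center, sigma, amp):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return amp * np.exp(
        -((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
        / (2 * sigma**2)
    )


class TestLocalMaxima:
    def test_single_blob_marks_its_center(self):
        arr = np.rint(_gaussian_blob((15, 15, 15), (7, 7, 7), 2.0, 200))
        mask = local_maxima_3d(_stack(arr), (3, 3, 3))
        assert mask.voxels[7, 7, 7]

    def test_distant_blobs_yield_two_clusters(self):
        from scipy import ndimage

        arr = np.rint(
            _gaussian_blob((15, 31, 31), (7, 7, 7), 1.5, 200)
            + _gaussian_blob((15, 31, 31), (7, 23, 23), 1.5, 200)
        )
        mask = local_maxima_3d(_stack(arr), (3, 3, 3))
        _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), bool))
        assert n == 2

    def test_blobs_within_kernel_in_every_axis_merge(self):
        # 4 px apart in x with kx=6: the dimmer peak sees the brighter
        # one inside its neighbourhood and is suppressed.
        from scipy import ndimage

        arr = np.rint(
            _gaussian_blob((11, 21, 21), (5, 10, 8), 1.5, 200)
            + _gaussian_blob((11, 21, 21), (5, 10, 12), 1.5, 180)
        )
        mask = local_maxima_3d(_stack(arr), (6, 6, 6))
        _, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), bool))
        assert n == 1


class TestBackgroundMode:
    def test_sparse_bright_voxels_do_not_move_the_mode(self):
        arr = np.zeros((5, 10, 10), dtype=np.uint8)
        arr.flat[:10] = 250
        assert background_mode(_stack(arr)) == 0

    def test_tie_breaks_toward_lower_intensity(self):
        arr = np.concatenate([np.full(500, 5), np.full(500, 20)])
        assert background_mode(_stack(arr.reshape(10, 10, 10))) == 5

    def test_uniform_noise_floor(self):
        rng = np.random.default_rng(0)
        arr = np.full((10, 20, 20), 7, dtype=np.uint8)
        idx = rng.choice(arr.size, 30, replace=False)
        arr.flat[idx] = rng.integers(100, 255, 30)
        assert background_mode(_stack(arr)) == 7


class TestStepGating:
    def test_cutoff_steps_with_signal_level(self):
        gating = StepGating(((50, 2), (255, 6)))
        assert step_gate_cutoff(5, 30, gating) == 7
        assert step_gate_cutoff(5, 200, gating) == 11

    def test_signal_beyond_last_bound_warns_and_uses_last_offset(self):
        gating = StepGating(((50, 2), (100, 6)))
        with pytest.warns(UserWarning, match="exceeds the last gating bound"):
            assert step_gate_cutoff(5, 250, gating) == 11

    def test_empty_steps_rejected(self):
        with pytest.raises(ValueError, match="empty step gating"):
            step_gate_cutoff(5, 30, StepGating(()))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            StepGating(((100, 2), (50, 4)))
        with pytest.raises(ValueError):
            StepGating(((100, -1),))


class TestSurroundMean:
    def test_constant_stack_single_voxel_mask(self):
        stack = _stack(np.full((9, 9, 9), 50))
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        assert surround_mean(stack, BinaryMask(mask), 3, 0) == pytest.approx(50)

    def test_gate_excludes_low_surround(self):
        arr = np.full((9, 9, 9), 10)
        arr[:, :, 4:] = 30
        stack = _stack(arr)
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        assert surround_mean(stack, BinaryMask(mask), 2, 20) == pytest.approx(30)

    def test_matches_brute_force_shell_enumeration(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 100, (5, 5, 5))
        stack = _stack(arr)
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        r, cutoff = 2, 30
        # brute force: enumerate voxels within euclidean distance r
        vals = []
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    d2 = (z - 2) ** 2 + (y - 2) ** 2 + (x - 2) ** 2
                    if 0 < d2 <= r * r:
                        vals.append(arr[z, y, x])
        vals = np.array(vals, float)
        expected = vals[vals >= cutoff].mean()
        assert surround_mean(stack, BinaryMask(mask), r, cutoff) == pytest.approx(
            expected
        )

    def test_all_false_mask_rejected(self):
        with pytest.raises(ValueError, match="no cells segmented"):
            surround_mean(_stack(np.zeros((3, 3, 3))), BinaryMask(np.zeros((3, 3, 3), bool)))


class TestTukeyThreshold:
    def test_zero_surround_gives_zero_fence(self):
        t = tukey_threshold(0.0)
        assert (t.q1, t.q3, t.threshold) == (0.0, 0.0, 0.0)

    def test_fence_is_the_exponential_closed_form(self):
        t = tukey_threshold(1.0)
        assert t.q1 == pytest.approx(math.log(4 / 3))
        assert t.q3 == pytest.approx(math.log(4))
        assert t.threshold == pytest.approx(3.0342, abs=5e-4)
        assert tukey_threshold(10.0).threshold == pytest.approx(30.342, abs=5e-3)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            tukey_threshold(-1.0)

    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(0, 1e4), c=st.floats(0, 100))
    def test_homogeneous_of_degree_one(self, x, c):
        assert tukey_threshold(c * x).threshold == pytest.approx(
            c * tukey_threshold(x).threshold, rel=1e-12, abs=1e-9
        )

    def test_ordering_invariant(self):
        t = tukey_threshold(5.0)
        assert t.threshold >= t.q3 >= t.q1 >= 0


class TestDetectSeeds:
    def test_counts_all_well_separated_cells(self, small_tdtomato_scene):
        scene = small_tdtomato_scene
        seeds = detect_seeds(scene.stack, "tdtomato", SPARSE_DETECTION)
        assert seeds.count == scene.truth[seeds.channel].count == 25

    def test_dim_channel_counts_match_too(self, small_egfp_scene):
        scene = small_egfp_scene
        seeds = detect_seeds(scene.stack, "egfp", SPARSE_DETECTION)
        assert seeds.count == scene.truth[seeds.channel].count

    def test_seed_positions_near_true_centroids(self, small_tdtomato_scene):
        scene = small_tdtomato_scene
        seeds = detect_seeds(scene.stack, "tdtomato", SPARSE_DETECTION)
        truth = scene.truth[seeds.channel].centroids
        pos = seeds.positions()
        for t in truth:
            d = np.abs(pos - t).max(axis=1).min()
            assert d <= 2.0  # within 2 px per axis of the true centre

    def test_constant_stack_yields_zero_seeds(self):
        stack = _stack(np.full((10, 20, 20), 3))
        assert detect_seeds(stack).count == 0

    def test_missing_channel_rejected(self, small_tdtomato_scene):
        with pytest.raises(KeyError):
            detect_seeds(small_tdtomato_scene.stack, "shg")

    def test_translation_equivariance(self, small_tdtomato_scene):
        raw = small_tdtomato_scene.stack["tdtomato"]
        shift = (2, 5, 3)
        shifted = np.roll(raw.voxels, shift, axis=(0, 1, 2))
        s0 = detect_seeds(raw, params=SPARSE_DETECTION)
        s1 = detect_seeds(
            ImageStack(shifted, raw.voxel_size, raw.channel), params=SPARSE_DETECTION
        )
        p0 = np.array(sorted(map(tuple, s0.positions() + np.array(shift))))
        p1 = np.array(sorted(map(tuple, s1.positions())))
        assert len(p0) == len(p1) == 25
        np.testing.assert_allclose(p0, p1, atol=0.75)

    def test_adding_one_bright_cell_adds_one_seed(self, small_tdtomato_scene):
        from ivmhisto.synth import _grid_sites

        scene = small_tdtomato_scene
        raw = scene.stack["tdtomato"]
        base = detect_seeds(raw, params=SPARSE_DETECTION).count
        # drop one extra bright cell on a free grid site: any two grid
        # sites are separated beyond the local-max kernel in >= 1 axis
        truth = scene.truth[raw.channel].centroids
        sites = _grid_sites(raw.shape)
        free = sites[
            [np.abs(truth - s).max(axis=1).min() > 4 for s in sites]
        ]
        cz, cy, cx = free[-1]
        zz, yy, xx = np.ogrid[: raw.shape[0], : raw.shape[1], : raw.shape[2]]
        blob = 220 * np.exp(
            -((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.0**2)
        )
        arr = np.clip(raw.voxels + np.rint(blob), 0, 255).astype(np.uint8)
        extra = detect_seeds(
            ImageStack(arr, raw.voxel_size, raw.channel), params=SPARSE_DETECTION
        ).count
        assert extra == base + 1


class TestSeedSet:
    def test_count_and_concat(self):
        a = SeedSet([])
        assert count_cells(a) == 0
        from ivmhisto.seed3d import Seed

        b = SeedSet([Seed((1, 2, 3), 10.0)] * 20)
        assert count_cells(b) == 20
        assert count_cells(SeedSet.concat(a, b, b)) == 40

    def test_csv_round_trip(self, tmp_path):
        from ivmhisto.seed3d import Seed

        ss = SeedSet([Seed((1.5, 2.25, 3.0), 200.0), Seed((0, 1, 2), 150.0)])
        write_seeds(ss, tmp_path / "s.csv")
        back = read_seeds(tmp_path / "s.csv")
        np.testing.assert_allclose(back.positions(), ss.positions())


def test_fence_factor_constant():
    assert TUKEY_FENCE_FACTOR == pytest.approx(math.log(4) + 1.5 * math.log(3))
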