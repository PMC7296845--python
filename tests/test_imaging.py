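import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from endoquant.errors import DegenerateFrameError, SpecValidationError
from endoquant.imaging import (
    FrameStack,
    classify_rois,
    count_clusters,
    estimate_threshold_static,
    estimate_threshold_timelapse,
    normalize_frame,
    quantify_static,
    quantify_timelapse,
    sum_above_threshold,
)
from endoquant.synthetic import ClusterSpec, StackSpec, simulate_stack


def naive_sint(values, k):
    """Independent oracle: double-loop enumeration of the Iverson sum."""
    passing = []
    for row in np.atleast_2d(values):
        for x in row:
            if x > k:
                passing.append(float(x))
    return math.fsum(passing)


class TestNormalizeFrame:
    def test_hand_enumerated_example(self):
        nf = normalize_frame(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        assert nf.source_median == 3.0
        assert nf.source_mad == 1.0
        assert np.array_equal(nf.values, [[-2.0, -1.0, 0.0, 1.0, 2.0]])

    def test_output_median_zero(self, rng):
        nf = normalize_frame(rng.normal(100, 10, size=(20, 20)))
        assert abs(np.median(nf.values)) < 1e-12

    def test_affine_invariance(self, rng):
        f = rng.normal(100, 10, size=(16, 16))
        a, b = 3.7, 42.0
        assert np.allclose(normalize_frame(f).values, normalize_frame(a * f + b).values,
                           rtol=1e-9, atol=1e-9)

    def test_constant_frame_degenerate(self):
        with pytest.raises(DegenerateFrameError) as exc:
            normalize_frame(np.full((2, 2), 7.0))
        assert exc.value.median == 7.0

    def test_mad_constant(self, rng):
        f = rng.normal(0, 1, size=(8, 8))
        plain = normalize_frame(f)
        consistent = normalize_frame(f, mad_constant=1.4826)
        assert np.allclose(consistent.values * 1.4826, plain.values)


class TestThresholds:
    def test_linear_interpolation_1_to_100(self):
        # closed form: position 1 + 0.99*(n-1) over {1..100} -> 99.01
        frames = [np.arange(1, 51, dtype=float).reshape(5, 10),
                  np.arange(51, 101, dtype=float).reshape(5, 10)]
        k = estimate_threshold_timelapse(frames, n_baseline=2)
        assert k == pytest.approx(99.01)

    def test_constant_baseline(self):
        frames = [np.full((4, 4), 2.5)] * 4
        assert estimate_threshold_timelapse(frames) == 2.5

    def test_permutation_invariance(self, rng):
        frames = [rng.normal(size=(6, 6)) for _ in range(4)]
        k1 = estimate_threshold_timelapse(frames)
        shuffled = [rng.permutation(f.ravel()).reshape(f.shape) for f in frames]
        k2 = estimate_threshold_timelapse(shuffled)
        assert k1 == pytest.approx(k2)

    def test_too_few_frames(self):
        with pytest.raises(SpecValidationError):
            estimate_threshold_timelapse([np.zeros((2, 2))] * 3, n_baseline=4)

    def test_static_matches_timelapse_on_same_pool(self, rng):
        img = rng.normal(size=(10, 10))
        assert estimate_threshold_static([img]) == estimate_threshold_timelapse(
            [img], n_baseline=1)

    def test_static_all_zero(self):
        assert estimate_threshold_static([np.zeros((5, 5))]) == 0.0

    def test_static_pooling_order_insensitive(self):
        a = np.arange(1, 51, dtype=float).reshape(5, 10)
        b = np.arange(51, 101, dtype=float).reshape(5, 10)
        pooled = np.arange(1, 101, dtype=float).reshape(10, 10)
        assert estimate_threshold_static([a, b]) == estimate_threshold_static([pooled])

    def test_empty_pool(self):
        with pytest.raises(SpecValidationError):
            estimate_threshold_static([])


class TestSumAboveThreshold:
    def test_direct_enumeration(self):
        assert sum_above_threshold(np.array([0.0, 1.0, 2.0, 3.0]), 1.0) == 5.0

    def test_all_below(self):
        assert sum_above_threshold(np.array([0.0, 1.0]), 5.0) == 0.0

    def test_k_below_min(self):
        v = np.array([1.0, 2.0, 3.0])
        assert sum_above_threshold(v, -1e9) == 6.0

    def test_strict_inequality(self):
        v = np.array([1.0, 1.0, 2.0])
        assert sum_above_threshold(v, 1.0) == 2.0
        assert sum_above_threshold(v, 1.0, strict=False) == 4.0

    @given(arrays(np.float64, (6, 6), elements=st.floats(0, 1e4)),
           st.floats(-10, 1e4))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_oracle(self, values, k):
        assert sum_above_threshold(values, k) == naive_sint(values, k)

    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 100)),
           st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_k(self, values, k1, dk):
        assert sum_above_threshold(values, k1 + dk) <= sum_above_threshold(values, k1)


def monotone_stack(gain=None):
    cluster = ClusterSpec(center=(8, 8), radius=3, onset_frame=6,
                          amplitude_curve=[40.0, 60.0, 80.0, 100.0])
    return simulate_stack(StackSpec(
        height=16, width=16, n_frames=10, background_level=100.0,
        background_checker_amplitude=10.0, background_noise_sd=0.0,
        clusters=[cluster], global_gain_drift=gain))


class TestQuantifyTimelapse:
    def test_zero_before_onset_monotone_after(self):
        result = quantify_timelapse(monotone_stack().stack)
        sint = result.per_frame_Sint
        assert np.all(sint[:6] == 0.0)
        assert np.all(np.diff(sint[6:]) >= 0)
        assert sint[-1] > 0

    def test_gain_drift_invariance(self):
        flat = quantify_timelapse(monotone_stack().stack)
        drift = quantify_timelapse(
            monotone_stack(gain=list(np.linspace(1.0, 2.5, 10))).stack)
        assert np.allclose(flat.per_frame_Sint, drift.per_frame_Sint, rtol=1e-9)
        assert flat.k == pytest.approx(drift.k, rel=1e-9)

    def test_affine_invariance_whole_pipeline(self, rng):
        frames = rng.normal(200, 20, size=(6, 12, 12))
        frames = np.clip(frames, 0, None)
        base = quantify_timelapse(FrameStack(frames=frames))
        scaled = quantify_timelapse(FrameStack(frames=3.0 * frames + 17.0))
        assert np.allclose(base.per_frame_Sint, scaled.per_frame_Sint, rtol=1e-9)

    def test_noise_only_stack_fluctuates_near_baseline(self, rng):
        # Monte-Carlo oracle: S_int of a pure-noise frame concentrates around
        # the mean exceedance mass of the normalized noise tail above k.
        frames = np.clip(rng.normal(100, 5, size=(40, 32, 32)), 0, None)
        result = quantify_timelapse(FrameStack(frames=frames))
        baseline = np.median(result.per_frame_Sint[:4])
        overall = np.median(result.per_frame_Sint)
        assert overall == pytest.approx(baseline, rel=0.5)

    def test_degenerate_frames_recorded(self):
        frames = np.ones((5, 4, 4)) * 50.0
        frames[4, 1, 1] = 60.0
        result = quantify_timelapse(FrameStack(frames=frames))
        assert result.degenerate_frames == [0, 1, 2, 3, 4]

    def test_degenerate_error_mode(self):
        frames = np.ones((4, 4, 4))
        with pytest.raises(DegenerateFrameError):
            quantify_timelapse(FrameStack(frames=frames), degenerate_fallback="error")


class TestQuantifyStatic:
    def test_test_equals_control_image(self, rng):
        img = rng.normal(100, 10, size=(20, 20))
        img = np.clip(img, 0, None)
        result = quantify_static([img], [img])
        nf = normalize_frame(img).values
        k = np.percentile(nf, 99)
        expected = nf[nf > k].sum()  # top-1% enumeration
        assert result.per_frame_Sint[0] == pytest.approx(expected)

    def test_below_control_k_gives_zero(self, rng):
        control = np.clip(rng.normal(100, 10, size=(20, 20)), 0, None)
        # mild test image: same median but tiny spread after normalization
        test = np.clip(rng.normal(100, 10, size=(20, 20)), 0, None)
        k_ctrl = np.percentile(normalize_frame(control).values, 99)
        test_n = normalize_frame(test).values
        result = quantify_static([test], [control])
        assert result.per_frame_Sint[0] == pytest.approx(test_n[test_n > k_ctrl].sum())

    def test_control_draw_exceedance_mass(self, rng):
        # Monte-Carlo oracle: a test image drawn from the control distribution
        # has ~1% of pixels above k on average.
        n_above = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            control = np.clip(r.normal(100, 10, size=(40, 40)), 0, None)
            test = np.clip(r.normal(100, 10, size=(40, 40)), 0, None)
            k = np.percentile(normalize_frame(control).values, 99)
            n_above.append((normalize_frame(test).values > k).mean())
        assert np.mean(n_above) == pytest.approx(0.01, rel=0.35)


class TestCountClusters:
    def test_planted_disks(self):
        clusters = [
            ClusterSpec(center=(6, 6), radius=2, onset_frame=0, amplitude_curve=[500.0]),
            ClusterSpec(center=(6, 20), radius=2, onset_frame=0, amplitude_curve=[500.0]),
            ClusterSpec(center=(20, 13), radius=2, onset_frame=0, amplitude_curve=[500.0]),
        ]
        sim = simulate_stack(StackSpec(height=26, width=26, n_frames=4,
                                       background_level=100.0,
                                       background_checker_amplitude=10.0,
                                       clusters=clusters))
        nf = normalize_frame(sim.stack.frames[0]).values
        count = count_clusters(nf, k=5.0, min_area=3)
        assert count.n_clusters == 3

    def test_empty_mask(self):
        count = count_clusters(np.zeros((10, 10)), k=1.0)
        assert count.n_clusters == 0

    def test_diagonal_touch_connectivity(self):
        img = np.zeros((6, 6))
        img[1, 1] = img[1, 2] = img[2, 1] = img[2, 2] = 10.0  # block A
        img[3, 3] = img[3, 4] = img[4, 3] = img[4, 4] = 10.0  # block B, corner-touching
        assert count_clusters(img, k=5.0, min_area=1, connectivity=8).n_clusters == 1
        assert count_clusters(img, k=5.0, min_area=1, connectivity=4).n_clusters == 2

    def test_min_area_filters(self):
        img = np.zeros((8, 8))
        img[0, 0] = 10.0           # area 1
        img[4:6, 4:6] = 10.0       # area 4
        count = count_clusters(img, k=5.0, min_area=2)
        assert count.n_clusters == 1
        assert np.all(count.cluster_labels[0, 0] == 0)

    def test_labels_respect_min_area_invariant(self):
        img = np.zeros((8, 8))
        img[1, 1:4] = 10.0
        count = count_clusters(img, k=5.0, min_area=2)
        for lab in range(1, count.n_clusters + 1):
            assert (count.cluster_labels == lab).sum() >= count.min_area


class TestClassifyRois:
    def test_planted_positive_negative(self):
        img = np.zeros((10, 10))
        img[2, 2] = 5.0
        roi_pos = np.zeros((10, 10), bool)
        roi_pos[0:4, 0:4] = True
        roi_neg = np.zeros((10, 10), bool)
        roi_neg[6:9, 6:9] = True
        result = classify_rois(img, [roi_pos, roi_neg], k=1.0)
        assert list(result.positive_flags) == [True, False]
        assert result.fraction_positive == 0.5

    def test_all_positive(self):
        img = np.full((4, 4), 10.0)
        rois = [np.eye(4, dtype=bool), ~np.eye(4, dtype=bool)]
        result = classify_rois(img, rois, k=1.0)
        assert result.fraction_positive == 1.0

    def test_roi_below_k_negative(self):
        img = np.full((4, 4), 0.5)
        roi = np.ones((4, 4), bool)
        result = classify_rois(img, [roi], k=1.0)
        assert not result.positive_flags[0]
        assert result.per_roi_Sint[0] == 0.0

    def test_shape_mismatch_error(self):
        with pytest.raises(SpecValidationError):
            classify_rois(np.zeros((4, 4)), [np.ones((5, 5), bool)], k=0.0)
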