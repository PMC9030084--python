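import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gaitstride import (
    SdatwConfig,
    SdatwSegmenter,
    StrideTemplate,
    WalkConfig,
    build_template,
    generate_walk,
    iou,
    neighborhood_features,
    sdatw_match,
)
from gaitstride import _dtw
from gaitstride.sdatw import _feature_matrix, extract_stride_signals, resample_to_length


class TestBuildTemplate:
    def test_mean_of_identical_rows_is_the_row(self):
        s = np.sin(np.linspace(0, 2 * np.pi, 16))
        tmpl = build_template([s, s], L=16)
        np.testing.assert_allclose(tmpl.values, s)

    def test_constant_strides_average_columnwise(self):
        tmpl = build_template([np.ones(10), np.full(25, 3.0)], L=12)
        np.testing.assert_allclose(tmpl.values, 2.0)

    def test_linear_resampling_oracle(self):
        # oracle: np.interp of [0,1,2,3] onto 8 points and of [0..14:2] onto
        # 8 points, averaged columnwise
        a = np.arange(4.0)
        b = np.arange(0.0, 16.0, 2.0)
        expected = (
            np.interp(np.linspace(0, 1, 8), np.linspace(0, 1, 4), a)
            + np.interp(np.linspace(0, 1, 8), np.linspace(0, 1, 8), b)
        ) / 2
        tmpl = build_template([a, b], L=8)
        np.testing.assert_allclose(tmpl.values, expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_template([])

    def test_default_length_is_median(self):
        tmpl = build_template([np.ones(30), np.ones(40), np.ones(50)])
        assert tmpl.L == 40

    def test_short_explicit_length_rejected(self):
        with pytest.raises(ValueError):
            build_template([np.arange(10.0)], L=4)

    def test_json_roundtrip(self, tmp_path, template):
        path = tmp_path / "t.json"
        template.to_json(path)
        back = StrideTemplate.from_json(path)
        np.testing.assert_allclose(back.values, template.values)
        assert back.L == template.L


class TestNeighborhoodFeatures:
    def test_constant_signal(self):
        f = neighborhood_features(np.full(20, 3.0), 10, SdatwConfig(window_halfwidth=2))
        np.testing.assert_allclose(f, [0.0, 0.0, 3.0])

    def test_unit_ramp_interior(self):
        sig = np.arange(30, dtype=float)
        f = neighborhood_features(sig, 15, SdatwConfig(window_halfwidth=2))
        np.testing.assert_allclose(f, [1.0, 4.0, 15.0])  # grad 1, range 2w, mean x[i]

    def test_edge_equals_replicated_padding(self):
        sig = np.arange(30, dtype=float)
        cfg = SdatwConfig(window_halfwidth=3)
        padded = np.concatenate([np.full(3, sig[0]), sig])
        np.testing.assert_allclose(
            neighborhood_features(sig, 0, cfg), neighborhood_features(padded, 3, cfg)
        )

    def test_wavelet_variant_shape_and_determinism(self):
        sig = np.sin(np.linspace(0, 6, 50))
        cfg = SdatwConfig(window_halfwidth=3, feature="wavelet")
        f1 = neighborhood_features(sig, 25, cfg)
        f2 = neighborhood_features(sig, 25, cfg)
        np.testing.assert_array_equal(f1, f2)
        assert f1.size == 4  # db1 approximation of a 7-sample window


class TestSdatwMatch:
    def test_self_match_spans_stream_with_zero_distance(self, template):
        matches = sdatw_match(template.values, template)
        assert len(matches) == 1
        assert (matches[0].interval.start, matches[0].interval.end) == (0, template.L)
        assert matches[0].accumulated_distance == pytest.approx(0.0, abs=1e-12)

    def test_three_copies_with_stretched_middle(self, template):
        s = template.values
        mid = resample_to_length(s, int(1.5 * len(s)))
        stream = np.concatenate([s, mid, s])
        joints = [0, len(s), len(s) + len(mid), len(stream)]
        matches = sdatw_match(stream, template)
        assert len(matches) == 3
        for m, (a, b) in zip(matches, zip(joints, joints[1:])):
            assert abs(m.interval.start - a) <= 3
            assert abs(m.interval.end - b) <= 3

    def test_half_stride_is_captured(self, template):
        s = template.values
        half = np.concatenate([s[: len(s) // 2], np.zeros(len(s) // 2)])
        stream = np.concatenate([s, s, half])
        matches = sdatw_match(stream, template)
        assert len(matches) == 3
        last = matches[-1].interval
        # the final match covers the half copy
        assert last.start <= 2 * len(s) + 3
        assert last.end > 2 * len(s) + len(s) // 4

    def test_short_stream_rejected(self, template):
        with pytest.raises(ValueError):
            sdatw_match(np.zeros(template.L // 2 - 1), template)

    def test_path_monotone_and_consistent_with_interval(self, template):
        w = generate_walk(WalkConfig(n_strides=5, cadence_hz=0.9, noise_sd=0.05, seed=3))
        stream = w.recording.channel("gyro", "coronal")
        cfg = SdatwConfig(close_gap_frac=0.0)  # raw match bounds = path bounds
        for m in sdatw_match(stream, template, cfg):
            path = np.asarray(m.path)
            assert np.all(np.diff(path[:, 0]) >= 0)
            assert np.all(np.diff(path[:, 1]) >= 0)
            assert path[0, 0] == m.interval.start
            assert path[-1, 0] == m.interval.end - 1
            assert path[0, 1] == 0 and path[-1, 1] == template.L - 1
        # with gap closing the interval may only grow, never shrink
        for m in sdatw_match(stream, template):
            path = np.asarray(m.path)
            assert path[0, 0] == m.interval.start
            assert path[-1, 0] <= m.interval.end - 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_intervals_ordered_and_non_overlapping_on_random_streams(self, template, seed):
        rng = np.random.default_rng(seed)
        stream = rng.normal(size=700)
        ivs = [m.interval for m in sdatw_match(stream, template)]
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start

    def test_accumulated_distance_monotone_along_path(self, template):
        # rerun the DP and check the prefix sums along each reported path
        cfg = SdatwConfig()
        w = generate_walk(WalkConfig(n_strides=4, cadence_hz=0.9, noise_sd=0.1, seed=9))
        stream = w.recording.channel("gyro", "coronal")
        F = _feature_matrix(stream, cfg)
        G = _feature_matrix(template.values, cfg)
        cost = cdist(F, G)
        for m in sdatw_match(stream, template, cfg):
            acc = np.cumsum([cost[i, j] for i, j in m.path])
            assert np.all(np.diff(acc) >= -1e-12)
            assert acc[-1] == pytest.approx(m.accumulated_distance, rel=1e-9)

    def test_amplitude_rescaling_invariance_with_normalized_features(self, template):
        cfg = SdatwConfig(normalize=True)
        w = generate_walk(WalkConfig(n_strides=8, cadence_hz=0.9, noise_sd=0.05, seed=4))
        stream = w.recording.channel("gyro", "coronal")
        a = [m.interval for m in sdatw_match(stream, template, cfg)]
        b = [m.interval for m in sdatw_match(stream * 12.5, template, cfg)]
        assert a == b


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_best_match_equals_brute_force_minimum(self, seed):
        """The reported best accumulated distance equals the minimum over all
        (start, end) open-begin-open-end DTW alignments."""
        rng = np.random.default_rng(seed)
        wt = generate_walk(WalkConfig(n_strides=6, cadence_hz=0.9, noise_sd=0.0, seed=seed))
        tmpl = build_template(
            extract_stride_signals(wt.recording, wt.truth.strides), L=60
        )
        stream = wt.recording.channel("gyro", "coronal")[:400] + rng.normal(0, 0.2, 400)
        cfg = SdatwConfig()
        cost = cdist(_feature_matrix(stream, cfg), _feature_matrix(tmpl.values, cfg))
        oracle = _dtw.brute_force_min_distance(cost)
        best = min(m.accumulated_distance for m in sdatw_match(stream, tmpl, cfg))
        assert best == pytest.approx(oracle, abs=1e-9)


def test_segmenter_estimator_roundtrip(clean_walk):
    seg = SdatwSegmenter(window_halfwidth=3)
    sigs = extract_stride_signals(clean_walk.recording, clean_walk.truth.strides)
    seg.fit(sigs)
    ivs = seg.predict_intervals(clean_walk.recording)
    assert len(ivs) == len(clean_walk.truth.strides)
    hits = sum(1 for p, t in zip(ivs, clean_walk.truth.strides) if iou(p, t) > 0.8)
    assert hits == len(ivs)
    assert seg.get_params()["window_halfwidth"] == 3
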