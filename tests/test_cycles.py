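"""Cycle segmentation, frame normalization, smoothing and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zfswim.config import RunConfig
from zfswim.cycles import (
    CurvatureProfile,
    CycleMetrics,
    WaveCycle,
    average_group_profiles,
    compare_groups,
    cycle_curvature_matrix,
    cycle_extrema,
    detect_cycles_auto,
    load_cycle_annotations,
    normalize_cycle_frames,
    normalize_to_wildtype,
    smooth_spatial,
    smooth_temporal,
)
from zfswim.errors import AnnotationError, ConfigError, CycleError
from zfswim.kinematics import PostureMetrics


class TestAnnotations:
    def test_two_rows(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("fish_id,start_frame,end_frame\nf1,0,59\nf1,80,111\n")
        cycles = load_cycle_annotations(p, n_frames=200)
        assert [(c.start_frame, c.end_frame) for c in cycles] == [(0, 59), (80, 111)]
        assert all(c.fish_id == "f1" for c in cycles)

    def test_out_of_bounds_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("fish_id,start_frame,end_frame\nf1,0,500\n")
        with pytest.raises(AnnotationError, match="beyond"):
            load_cycle_annotations(p, n_frames=100)

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        p = tmp_path / "c.csv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert load_cycle_annotations(p) == []
        assert "empty" in caplog.text

    def test_malformed_row_reports_position(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("fish_id,start_frame,end_frame\nf1,0,59\nf1,abc,99\n")
        with pytest.raises(AnnotationError, match="row 2"):
            load_cycle_annotations(p)

    def test_overlap_warns_but_loads(self, tmp_path, caplog):
        p = tmp_path / "c.csv"
        p.write_text("fish_id,start_frame,end_frame\nf1,0,59\nf1,50,99\n")
        with caplog.at_level("WARNING"):
            assert len(load_cycle_annotations(p)) == 2
        assert "overlap" in caplog.text


class TestAutoDetection:
    def test_four_periods_detected(self, cfg):
        x = np.arange(4 * 80)
        series = 0.55 + 0.01 * np.cos(2 * np.pi * (x + 13) / 80)
        cycles = detect_cycles_auto(series, cfg)
        assert 3 <= len(cycles) <= 4
        spans = [c.span for c in cycles[1:]]  # first may be partial
        assert all(abs(s - 80) <= 3 for s in spans)

    def test_constant_series_gives_no_cycles(self, cfg):
        assert detect_cycles_auto(np.full(200, 0.5), cfg) == []

    def test_single_period_covered(self, cfg):
        x = np.arange(81)
        series = 0.55 + 0.01 * np.cos(2 * np.pi * x / 80)
        cycles = detect_cycles_auto(series, cfg)
        assert len(cycles) == 1
        assert abs(cycles[0].start_frame - 0) <= 3
        assert abs(cycles[0].end_frame - 80) <= 3


class TestNormalizeFrames:
    def test_exact_span_is_identity(self):
        np.testing.assert_array_equal(
            normalize_cycle_frames(10, 39, 30, 100), np.arange(10, 40)
        )

    def test_long_span_uniform_subsample(self):
        idx = normalize_cycle_frames(0, 58, 30, 100)
        np.testing.assert_array_equal(idx, np.arange(0, 59, 2))

    def test_short_span_extended_evenly(self):
        # 26-frame span needs 4 extra: 2 before, 2 after, contiguous
        idx = normalize_cycle_frames(10, 35, 30, 100)
        np.testing.assert_array_equal(idx, np.arange(8, 38))

    def test_odd_deficit_prefers_after(self):
        idx = normalize_cycle_frames(10, 36, 30, 100)  # 27-frame span, deficit 3
        np.testing.assert_array_equal(idx, np.arange(9, 39))

    def test_extension_clipped_at_video_start(self):
        idx = normalize_cycle_frames(1, 26, 30, 100)  # only 1 frame available before
        np.testing.assert_array_equal(idx, np.arange(0, 30))

    def test_impossible_extension_raises(self):
        with pytest.raises(CycleError):
            normalize_cycle_frames(0, 9, 30, 20)

    @given(
        start=st.integers(0, 50),
        span=st.integers(1, 120),
        target=st.integers(2, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_target_sorted_unique(self, start, span, target):
        end = start + span - 1
        n_frames = 400
        idx = normalize_cycle_frames(start, end, target, n_frames)
        assert len(idx) == target
        assert np.all(np.diff(idx) > 0)
        assert idx[0] >= 0 and idx[-1] < n_frames


class TestSmoothing:
    def test_constant_column_unchanged(self):
        C = np.full((20, 30), 7.0)
        np.testing.assert_allclose(smooth_spatial(C, 0.2), C, atol=1e-8)
        np.testing.assert_allclose(smooth_temporal(C, 0.15), C, atol=1e-8)

    def test_low_frequency_preserved(self):
        n = 64
        x = np.sin(2 * np.pi * 0.05 * np.arange(n))
        out = smooth_temporal(x[None, :], 0.2)[0]
        assert np.ptp(out) == pytest.approx(np.ptp(x), rel=0.05)

    def test_nyquist_spikes_crushed(self):
        col = 10.0 * (-1.0) ** np.arange(32)
        out = smooth_spatial(np.tile(col[:, None], (1, 3)), 0.2)
        assert np.ptp(out[:, 1]) <= 0.2 * np.ptp(col)

    def test_single_outlier_attenuated(self):
        row = np.zeros(30)
        row[15] = 10.0
        out = smooth_temporal(row[None, :], 0.15)[0]
        assert out[15] <= 0.5 * row[15]

    def test_double_smoothing_nearly_idempotent_in_band(self):
        x = np.sin(2 * np.pi * 0.03 * np.arange(100))
        once = smooth_temporal(x[None, :], 0.15)[0]
        twice = smooth_temporal(once[None, :], 0.15)[0]
        e1, e2 = np.sum(once**2), np.sum(twice**2)
        assert abs(e2 - e1) / e1 < 0.10

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ConfigError):
            smooth_spatial(np.zeros((20, 30)), 0.7)


def _metrics_from_curvature(curv_by_frame, tail=0.5):
    return {
        f: PostureMetrics(f, np.asarray(k, float), tail, (0.0, 0.0), 100.0)
        for f, k in curv_by_frame.items()
    }


class TestCurvatureMatrix:
    def _cycle(self, start, end, target, n_frames=200):
        wc = WaveCycle("f", "g", start, end)
        wc.normalized_frames = normalize_cycle_frames(start, end, target, n_frames)
        return wc

    def test_shape_is_points_by_target(self, cfg):
        fm = _metrics_from_curvature({f: np.zeros(20) for f in range(40)})
        prof = cycle_curvature_matrix(fm, self._cycle(0, 29, 30), cfg)
        assert prof.C.shape == (20, 30)

    def test_straight_fish_all_zero(self, cfg):
        fm = _metrics_from_curvature({f: np.zeros(20) for f in range(40)})
        prof = cycle_curvature_matrix(fm, self._cycle(0, 29, 30), cfg)
        np.testing.assert_allclose(prof.C, 0.0, atol=1e-9)

    def test_missing_posture_rejects_cycle(self, cfg):
        fm = _metrics_from_curvature({f: np.zeros(20) for f in range(25)})
        with pytest.raises(CycleError, match="frame"):
            cycle_curvature_matrix(fm, self._cycle(0, 29, 30), cfg)

    def test_traveling_wave_ridge_moves_toward_tail(self, cfg):
        """The curvature peak row advances head->tail across the cycle."""
        n_pts, n_t = 20, 30
        fm = {}
        for f in range(n_t):
            k = np.zeros(n_pts)
            center = 3 + (f / (n_t - 1)) * 13  # peak location drifts tailward
            k += 10 * np.exp(-0.5 * ((np.arange(n_pts) - center) / 2.0) ** 2)
            fm[f] = PostureMetrics(f, k, 0.5, (0.0, 0.0), 100.0)
        prof = cycle_curvature_matrix(fm, self._cycle(0, n_t - 1, n_t), cfg)
        argmax_rows = prof.C.argmax(axis=0)
        assert np.all(np.diff(argmax_rows) >= 0)
        assert argmax_rows[-1] > argmax_rows[0]

    def test_entries_nonnegative(self, cfg):
        rng = np.random.default_rng(0)
        fm = _metrics_from_curvature(
            {f: np.abs(rng.normal(5, 3, 20)) for f in range(30)}
        )
        prof = cycle_curvature_matrix(fm, self._cycle(0, 29, 30), cfg)
        assert (prof.C >= 0).all()


class TestGroupAveraging:
    def test_single_cycle_mean_is_itself(self):
        C = np.arange(600.0).reshape(20, 30)
        mean_C, mean_off = average_group_profiles(
            [CurvatureProfile(C)], [np.linspace(0.4, 0.6, 30)], "g"
        )
        np.testing.assert_array_equal(mean_C, C)

    def test_two_cycle_mean(self):
        a = CurvatureProfile(np.zeros((20, 30)))
        b = CurvatureProfile(np.full((20, 30), 10.0))
        mean_C, _ = average_group_profiles([a, b], [np.zeros(30), np.zeros(30)], "g")
        np.testing.assert_allclose(mean_C, 5.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            average_group_profiles([], [], "g")


class TestCycleExtrema:
    def test_trivial_flat_cycle(self):
        m = cycle_extrema(
            CurvatureProfile(np.zeros((20, 30))),
            np.full(30, 0.5),
            np.tile([3.0, 4.0], (30, 1)),
        )
        assert (m.max_curvature, m.min_tail_offset, m.travel_distance) == (0.0, 0.5, 0.0)

    def test_larger_amplitude_larger_max(self):
        base = np.random.default_rng(1).uniform(0, 1, (20, 30))
        m1 = cycle_extrema(CurvatureProfile(4 * base), np.full(30, 0.5), np.zeros((30, 2)))
        m2 = cycle_extrema(CurvatureProfile(9 * base), np.full(30, 0.5), np.zeros((30, 2)))
        assert m2.max_curvature > m1.max_curvature

    def test_min_never_exceeds_first_frame(self):
        offs = np.array([0.52, 0.49, 0.45, 0.47, 0.55])
        m = cycle_extrema(CurvatureProfile(np.zeros((20, 5))), offs, np.zeros((5, 2)))
        assert m.min_tail_offset <= offs[0]


class TestWildtypeNormalization:
    def _metrics(self, k, to, td, n=4):
        return [CycleMetrics(k, to, td) for _ in range(n)]

    def test_wildtype_relative_mean_is_one(self):
        rel = normalize_to_wildtype({"wt": self._metrics(10, 0.5, 30)}, "wt")
        assert rel["wt"] == {
            "max_curvature": 1.0, "min_tail_offset": 1.0, "travel_distance": 1.0,
        }

    def test_half_mean_gives_half(self):
        rel = normalize_to_wildtype(
            {"wt": self._metrics(10, 0.5, 30), "mut": self._metrics(5, 0.25, 15)}, "wt"
        )
        assert rel["mut"]["max_curvature"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        groups = {"wt": self._metrics(10, 0.5, 30), "mut": self._metrics(7, 0.6, 21)}
        scaled = {
            g: [CycleMetrics(3 * m.max_curvature, 3 * m.min_tail_offset, 3 * m.travel_distance) for m in ms]
            for g, ms in groups.items()
        }
        assert normalize_to_wildtype(groups, "wt") == normalize_to_wildtype(scaled, "wt")

    def test_zero_wildtype_mean_raises(self):
        with pytest.raises(ValueError):
            normalize_to_wildtype({"wt": self._metrics(0.0, 0.5, 30)}, "wt")


class TestStudentT:
    def test_identical_samples(self):
        r = compare_groups([1, 2, 3], [1, 2, 3])
        assert (r.t, r.p, r.significant) == (0.0, 1.0, False)

    def test_hand_computed_pooled_t(self):
        """(1..5) vs (2..6): pooled SE = 1, t = -1, df = 8, p = 0.3466."""
        r = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.t == pytest.approx(-1.0)
        assert r.p == pytest.approx(0.3466, abs=0.001)
        assert not r.significant

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 9)
        r = compare_groups(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)
        rw = compare_groups(x, y, equal_variance=False)
        refw = stats.ttest_ind(x, y, equal_var=False)
        assert rw.t == pytest.approx(refw.statistic)
        assert rw.p == pytest.approx(refw.pvalue)

    def test_zero_variance_unequal_means_significant(self):
        r = compare_groups([2.0, 2.0, 2.0], [5.0, 5.0, 5.0])
        assert r.significant
        assert 0 < r.p < np.finfo(float).tiny

    def test_too_small_samples_raise(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
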