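import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import involvement_oracle

from fourap.ios_analysis import (
    DTTStack,
    IOSSeries,
    compute_dtt,
    involvement_map,
    onset_region,
    place_roi,
    render_pseudocolor,
    roi_intensity,
    sle_area,
)


def make_series(frames, n_control=20):
    frames = np.asarray(frames)
    times = (np.arange(len(frames)) - n_control + 0.5) / 2.0
    return IOSSeries(frames=frames, frame_times_s=times, n_control_frames=n_control)


def make_dtt(values, n_control=0):
    values = np.asarray(values, dtype=np.float32)
    times = (np.arange(len(values)) - n_control + 0.5) / 2.0
    return DTTStack(values=values, frame_times_s=times, n_control_frames=n_control)


class TestComputeDtt:
    def test_identical_frames_give_zero(self):
        frames = np.full((30, 8, 8), 100, dtype=np.uint8)
        dtt = compute_dtt(make_series(frames))
        assert np.allclose(dtt.values, 0.0)

    def test_two_percent_step(self):
        frames = np.full((25, 4, 4), 100, dtype=np.uint8)
        frames[24] = 102
        dtt = compute_dtt(make_series(frames))
        assert dtt.values[24] == pytest.approx(2.0)

    def test_stack_shorter_than_control_window_rejected(self):
        frames = np.full((10, 4, 4), 100, dtype=np.uint8)
        with pytest.raises(ValueError, match="control window"):
            make_series(frames, n_control=20)

    def test_saturated_pixels_flagged(self):
        frames = np.full((25, 4, 4), 100, dtype=np.uint8)
        frames[:, 0, 0] = 255
        dtt = compute_dtt(make_series(frames))
        assert np.isnan(dtt.values[:, 0, 0]).all()
        assert np.isfinite(dtt.values[:, 1:, :]).all()

    def test_zero_control_pixels_flagged(self):
        frames = np.full((25, 4, 4), 100, dtype=np.uint8)
        frames[:, 1, 1] = 0
        dtt = compute_dtt(make_series(frames))
        assert np.isnan(dtt.values[:, 1, 1]).all()

    def test_invariant_under_illumination_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(80, 120, (30, 6, 6))
        a = compute_dtt(make_series(base))
        b = compute_dtt(make_series(base * 1.7))
        np.testing.assert_allclose(a.values, b.values, atol=1e-4)

    def test_noise_only_roi_fluctuation_below_0p1_pct(self, masks, control_spec):
        # synthetic noise-only series: per-ROI dT/T stays below the 0.1 % bound
        from fourap.synthetic_data.ios import generate_ios_series
        from fourap.synthetic_data.lfp import GroundTruthEvent

        silent = control_spec.with_overrides(
            ios_peak_dtt_pct={r: (0.0, 0.0, 0.0) for r in masks.labels()},
            area_fraction_pct={r: (0.0, 0.0, 0.0) for r in masks.labels()},
        )
        event = GroundTruthEvent(0.0, 50.0, 1.5, "EC", "baseline")
        series, _ = generate_ios_series(event, masks, silent, seed=0)
        dtt = compute_dtt(series)
        for summary in roi_intensity(dtt, masks).values():
            assert np.nanstd(summary.timecourse_pct) < 0.1
            assert abs(np.nanmean(summary.timecourse_pct[:20])) < 0.05


class TestInvolvementMap:
    def _stack_with_run(self, run_length, value=1.5, n_frames=30):
        values = np.zeros((n_frames, 3, 3), dtype=np.float32)
        values[5 : 5 + run_length, 1, 1] = value
        return make_dtt(values)

    def test_nine_consecutive_frames_not_involved(self):
        inv = involvement_map(self._stack_with_run(9))
        assert not inv[1, 1]

    def test_ten_consecutive_frames_involved(self):
        inv = involvement_map(self._stack_with_run(10))
        assert inv[1, 1]
        assert inv.sum() == 1

    def test_just_below_threshold_never_involved(self):
        inv = involvement_map(self._stack_with_run(100, value=0.99, n_frames=110))
        assert not inv.any()

    def test_interrupted_run_not_involved(self):
        values = np.zeros((30, 2, 2), dtype=np.float32)
        values[3:12, 0, 0] = 2.0  # 9 frames
        values[13:22, 0, 0] = 2.0  # interrupted, then 9 more
        inv = involvement_map(make_dtt(values))
        assert not inv[0, 0]

    def test_persistence_exceeding_stack_warns(self):
        values = np.full((5, 2, 2), 3.0, dtype=np.float32)
        with pytest.warns(UserWarning, match="persistence"):
            inv = involvement_map(make_dtt(values), persistence_frames=10)
        assert not inv.any()

    def test_nan_breaks_runs(self):
        values = np.full((30, 1, 1), 2.0, dtype=np.float32)
        values[::5, 0, 0] = np.nan
        inv = involvement_map(make_dtt(values))
        assert not inv[0, 0]

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            values = rng.normal(0.8, 0.6, (40, 16, 16)).astype(np.float32)
            fast = involvement_map(make_dtt(values))
            slow = involvement_oracle(values, 1.0, 10)
            np.testing.assert_array_equal(fast, slow)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        threshold=st.floats(0.5, 2.0),
        persistence=st.integers(1, 15),
    )
    def test_matches_bruteforce_oracle_property(self, seed, threshold, persistence):
        rng = np.random.default_rng(seed)
        values = rng.normal(threshold, 0.5, (20, 8, 8)).astype(np.float32)
        fast = involvement_map(
            make_dtt(values), threshold_pct=threshold, persistence_frames=persistence
        )
        slow = involvement_oracle(values, threshold, persistence)
        np.testing.assert_array_equal(fast, slow)

    def test_area_monotone_in_amplitude(self, masks):
        areas = []
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.05, (40, 240, 320)).astype(np.float32)
        for amp in (0.5, 0.9, 1.1, 2.0):
            values = noise.copy()
            values[10:30][:, masks["EC"]] += amp
            inv = involvement_map(make_dtt(values))
            areas.append(sle_area(inv, masks)["EC"])
        assert all(a <= b + 1e-9 for a, b in zip(areas, areas[1:]))


class TestSleArea:
    def test_no_involvement(self, masks):
        inv = np.zeros(masks.shape, dtype=bool)
        areas = sle_area(inv, masks)
        assert all(v == 0.0 for v in areas.values())

    def test_full_involvement(self, masks):
        inv = np.ones(masks.shape, dtype=bool)
        areas = sle_area(inv, masks)
        assert all(v == 100.0 for v in areas.values())

    def test_counting_oracle_30pct_subset(self, masks):
        rng = np.random.default_rng(7)
        mask = masks["EC"]
        idx = np.flatnonzero(mask.ravel())
        n_pick = int(round(0.30 * len(idx)))
        inv = np.zeros(mask.size, dtype=bool)
        inv[rng.choice(idx, n_pick, replace=False)] = True
        area = sle_area(inv.reshape(mask.shape), masks)["EC"]
        quantum = 100.0 / mask.sum()
        assert abs(area - 30.0) <= quantum


class TestRoiIntensity:
    def test_zero_stack(self, masks):
        values = np.zeros((30, 240, 320), dtype=np.float32)
        out = roi_intensity(make_dtt(values, n_control=20), masks)
        assert all(s.peak_pct == 0.0 for s in out.values())

    def test_uniform_plateau_recovered(self, masks):
        values = np.zeros((30, 240, 320), dtype=np.float32)
        values[22:28] = 2.0
        out = roi_intensity(make_dtt(values, n_control=20), masks)
        for s in out.values():
            assert s.peak_pct == pytest.approx(2.0)

    def test_small_mask_shrinks_roi_with_warning(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:18, 10:18] = True  # 8x8 < 20x20
        values = np.zeros((25, 50, 50), dtype=np.float32)
        with pytest.warns(UserWarning, match="shrunk"):
            out = roi_intensity(make_dtt(values, n_control=20), {"X": mask})
        r0, c0, h, w = out["X"].roi_box
        assert h < 20 and mask[r0 : r0 + h, c0 : c0 + w].all()

    def test_place_roi_empty_mask(self):
        with pytest.raises(ValueError, match="empty"):
            place_roi(np.zeros((10, 10), dtype=bool))


class TestOnsetRegion:
    def _dtt_with_latencies(self, masks, latencies, amp=2.0):
        values = np.zeros((40, 240, 320), dtype=np.float32)
        for region, lat in latencies.items():
            values[20 + lat :][:, masks[region]] = amp
        return make_dtt(values, n_control=20)

    def test_leading_region_wins(self, masks):
        dtt = self._dtt_with_latencies(masks, {"EC": 0, "PC": 2, "TC": 4, "SUB": 6})
        assert onset_region(dtt, masks) == "EC"

    def test_simultaneous_rise_uses_region_order(self, masks):
        dtt = self._dtt_with_latencies(masks, {r: 0 for r in masks.labels()})
        assert onset_region(dtt, masks) == masks.labels()[0]

    def test_tie_broken_by_amplitude(self, masks):
        values = np.zeros((40, 240, 320), dtype=np.float32)
        values[20:][:, masks["PC"]] = 1.0
        values[20:][:, masks["TC"]] = 3.0
        assert onset_region(make_dtt(values, n_control=20), masks) == "TC"

    def test_subthreshold_stack_gives_none(self, masks):
        values = np.full((40, 240, 320), 0.1, dtype=np.float32)
        assert onset_region(make_dtt(values, n_control=20), masks) is None


class TestRenderPseudocolor:
    def test_zero_stack_uniform_color(self, tmp_path):
        values = np.zeros((5, 8, 8), dtype=np.float32)
        path = render_pseudocolor(make_dtt(values), tmp_path / "out.tif")
        import tifffile

        rgb = tifffile.imread(path)
        assert rgb.shape == (5, 8, 8, 3)
        for frame in rgb:
            assert len(np.unique(frame.reshape(-1, 3), axis=0)) == 1

    def test_frame_count_preserved_gif(self, tmp_path):
        values = np.random.default_rng(0).normal(1, 1, (7, 8, 8)).astype(np.float32)
        path = render_pseudocolor(make_dtt(values), tmp_path / "out.gif")
        from PIL import Image

        with Image.open(path) as im:
            assert im.n_frames == 7

    def test_deterministic_bytes(self, tmp_path):
        values = np.random.default_rng(1).normal(1, 1, (6, 8, 8)).astype(np.float32)
        p1 = render_pseudocolor(make_dtt(values), tmp_path / "a.gif")
        p2 = render_pseudocolor(make_dtt(values), tmp_path / "b.gif")
        assert p1.read_bytes() == p2.read_bytes()
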