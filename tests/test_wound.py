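import numpy as np
import pandas as pd
import pytest

from woundchip import wound as W

RNG = np.random.default_rng(42)


def frame_with_band(width=64, size=256, noise_hi=2000.0, noise_lo=20.0, seed=0):
    """Textured monolayer with a smooth central vertical band."""
    rng = np.random.default_rng(seed)
    img = 20000.0 + rng.normal(0, noise_hi, (size, size))
    lo = size // 2 - width // 2
    band = slice(lo, lo + width)
    img[:, band] = 20000.0 + rng.normal(0, noise_lo, (size, width))
    truth = np.zeros((size, size), dtype=bool)
    truth[:, band] = True
    return img, truth


class TestSegmentWound:
    def test_smooth_band_recovered_with_high_iou(self):
        img, truth = frame_with_band()
        seg = W.segment_wound(img)
        assert seg.flag is None
        inter = (seg.mask & truth).sum()
        union = (seg.mask | truth).sum()
        assert inter / union >= 0.9

    def test_fully_textured_frame_flags_empty_wound(self):
        img = RNG.normal(20000.0, 2000.0, (128, 128))
        seg = W.segment_wound(img)
        assert seg.flag == "empty"
        assert seg.area_px == 0.0

    def test_fully_smooth_frame_flags_degenerate(self):
        img = np.full((128, 128), 5000.0) + RNG.normal(0, 1.0, (128, 128))
        seg = W.segment_wound(img)
        assert seg.flag == "degenerate"
        assert seg.mask.all()

    def test_rgb_input_rejected(self):
        with pytest.raises(ValueError):
            W.segment_wound(np.zeros((8, 8, 3)))

    def test_end_to_end_iou_against_renderer_ground_truth(self, control_run):
        truth, stack = control_run
        seg = W.segment_wound(stack[0])
        tm = truth.wound_masks[0]
        assert ((seg.mask & tm).sum() / (seg.mask | tm).sum()) >= 0.9


class TestClosureCurve:
    @staticmethod
    def shrinking_band_stack(n_frames=13, size=192, width0=96):
        frames, truths = [], []
        for k in range(n_frames):
            w = max(int(round(width0 * (1 - k / (n_frames - 1)))), 0)
            if w > 0:
                img, t = frame_with_band(width=w, size=size, seed=k)
            else:
                img = np.random.default_rng(k).normal(20000.0, 2000.0, (size, size))
                t = np.zeros((size, size), dtype=bool)
            frames.append(img)
            truths.append(t)
        return np.stack(frames), np.stack(truths)

    def test_first_frame_normalized_area_is_one(self):
        stack, _ = self.shrinking_band_stack()
        curve = W.closure_curve(stack, 60.0)
        assert curve.normalized_area[0] == 1.0
        assert curve.closure_percent[0] == 0.0

    def test_linear_shrink_reaches_full_closure(self):
        stack, _ = self.shrinking_band_stack()
        curve = W.closure_curve(stack, 60.0)
        assert curve.closure_percent[-1] == pytest.approx(100.0, abs=1.0)

    def test_closure_invariant_to_affine_intensity_rescale(self):
        stack, _ = self.shrinking_band_stack(n_frames=4)
        c1 = W.closure_curve(stack, 60.0)
        c2 = W.closure_curve(0.5 * stack + 3000.0, 60.0)
        assert np.allclose(c1.area_px, c2.area_px)

    def test_zero_initial_area_rejected(self):
        flat = RNG.normal(20000.0, 2000.0, (3, 64, 64))
        with pytest.raises(ZeroDivisionError):
            W.closure_curve(flat, 10.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            W.closure_curve(np.zeros((1, 32, 32)), 10.0)


class TestClosureRate:
    @staticmethod
    def curve_from_percent(percent, dt_h=1.0):
        percent = np.asarray(percent, dtype=float)
        t = np.arange(len(percent)) * dt_h
        norm = 1.0 - percent / 100.0
        return W.ClosureCurve(
            time_h=t, area_px=norm * 1e4, normalized_area=norm,
            closure_percent=percent, flags=[None] * len(percent),
        )

    def test_exact_line_recovers_slope(self):
        curve = self.curve_from_percent(3.0 * np.arange(10))
        assert W.closure_rate(curve) == pytest.approx(3.0)

    def test_constant_curve_has_zero_rate(self):
        curve = self.curve_from_percent(np.full(10, 5.0))
        assert W.closure_rate(curve) == pytest.approx(0.0)

    def test_default_window_stops_at_full_closure(self):
        # 10 %/h for 10 h then saturated at 100%: the plateau must not
        # dilute the fitted slope
        percent = np.concatenate([10.0 * np.arange(11), np.full(10, 100.0)])
        curve = self.curve_from_percent(percent)
        assert W.closure_rate(curve) == pytest.approx(10.0, rel=0.02)

    def test_degenerate_window_rejected(self):
        curve = self.curve_from_percent([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            W.closure_rate(curve, window=(10.0, 20.0))


class TestKymograph:
    def test_twelve_hour_ten_minute_stack_yields_72_rows(self):
        stack = RNG.normal(100.0, 10.0, (72, 64, 96))
        km = W.kymograph(stack, (10, 8, 50, 88))
        assert km.data.shape == (72, 80)
        assert km.n_lines == 7

    def test_temporally_constant_stack_gives_identical_rows(self):
        frame = RNG.normal(100.0, 10.0, (48, 64))
        stack = np.repeat(frame[None], 5, axis=0)
        km = W.kymograph(stack, (4, 4, 44, 60))
        assert np.allclose(km.data, km.data[0])

    def test_single_bright_column_maps_to_single_kymograph_column(self):
        stack = np.zeros((4, 32, 48))
        stack[:, :, 20] = 255.0
        km = W.kymograph(stack, (0, 0, 32, 48))
        assert np.all(km.data[:, 20] == 255.0)
        km.data[:, 20] = 0.0
        assert np.all(km.data == 0.0)

    def test_mirrored_stack_gives_mirrored_kymograph(self):
        stack = RNG.normal(100.0, 10.0, (6, 40, 64))
        km = W.kymograph(stack, (0, 0, 40, 64))
        km_mirror = W.kymograph(stack[:, :, ::-1], (0, 0, 40, 64))
        assert np.allclose(km_mirror.data, km.data[:, ::-1])

    def test_roi_taller_than_frame_rejected(self):
        with pytest.raises(ValueError):
            W.kymograph(np.zeros((3, 32, 32)), (0, 0, 40, 30))

    def test_more_lines_than_roi_height_rejected(self):
        with pytest.raises(ValueError):
            W.kymograph(np.zeros((3, 32, 32)), (0, 0, 5, 30), n_lines=7)


def tracks_df(paths):
    rows = []
    for cid, path in enumerate(paths):
        for frame, (x, y) in enumerate(path):
            rows.append(dict(frame=frame, cell_id=cid, x=x, y=y))
    return pd.DataFrame(rows)


class TestDirectedness:
    def test_straight_tracks_hit_the_cosine_limits(self):
        df = tracks_df([
            [(0, 0), (1, 0), (2, 0)],   # rightward -> +1
            [(0, 0), (-1, 0), (-2, 0)],  # leftward -> -1
            [(0, 0), (0, 1), (0, 2)],   # vertical -> 0
        ])
        stats = W.directedness(df)
        per = stats.per_cell.set_index("cell_id")["mean_step_cos"]
        assert per[0] == pytest.approx(1.0)
        assert per[1] == pytest.approx(-1.0)
        assert per[2] == pytest.approx(0.0)

    def test_stationary_cell_excluded_with_flag(self):
        df = tracks_df([[(0, 0), (0, 0), (0, 0)], [(0, 0), (1, 0)]])
        stats = W.directedness(df)
        assert stats.n_excluded == 1
        assert len(stats.per_cell) == 1

    def test_mirrored_cohort_directedness_sums_to_zero(self):
        rng = np.random.default_rng(3)
        steps = rng.normal(0, 1, (20, 30, 2))
        paths = np.cumsum(steps, axis=1)
        df = tracks_df([list(map(tuple, p)) for p in paths])
        mirrored = df.assign(x=-df["x"])
        s1 = W.directedness(df)
        s2 = W.directedness(mirrored)
        assert s1.cohort_mean + s2.cohort_mean == pytest.approx(0.0, abs=1e-12)

    def test_zero_displacement_steps_are_skipped(self):
        df = tracks_df([[(0, 0), (0, 0), (1, 0)]])
        stats = W.directedness(df)
        assert stats.per_cell["mean_step_cos"].iloc[0] == pytest.approx(1.0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="cell_id"):
            W.TrackSet(pd.DataFrame(dict(frame=[0], x=[0.0], y=[0.0])))

    def test_non_monotone_frames_rejected(self):
        df = pd.DataFrame(dict(frame=[0, 0], cell_id=[1, 1], x=[0.0, 1.0], y=[0.0, 0.0]))
        with pytest.raises(ValueError, match="non-monotone"):
            W.TrackSet(df)
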