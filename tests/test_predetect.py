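import numpy as np
import pytest

from thermark import DetectorParams, ThermalVideo, run_preliminary_detection
from thermark.predetect import (
    BlobTrack,
    associate_blobs,
    binary_close,
    compute_blob_mask,
    compute_cooldown,
    compute_cooldown_all,
    compute_difference,
    compute_floor_median,
    compute_mouse_mask,
    disk_footprint,
    finalize_tracks,
    init_background,
    refine_blobs,
    update_background,
    update_inpainted,
)
from thermark.thermsim import config_from_preset, render_session
from thermark.thermal_io import apply_calibration

P = DetectorParams()
FPS = 8.66


def full_floor(shape):
    return np.ones(shape, dtype=bool)


class TestBackground:
    def test_static_video(self):
        frames = np.full((200, 8, 8), 25.0, dtype=np.float32)
        assert np.array_equal(init_background(frames, FPS, P), frames[0])

    def test_moving_blob_erased_by_min(self):
        # a 35 degC blob visits each column for a few frames only
        n = int(round(P.bg_init_s * FPS))
        frames = np.full((n, 6, 12), 25.0, dtype=np.float32)
        for i in range(n):
            frames[i, 2:4, (i // 15) % 12] = 35.0
        b0 = init_background(frames, FPS, P)
        assert np.allclose(b0, 25.0)
        assert np.array_equal(b0, frames.min(axis=0))

    def test_short_video_rejected(self):
        with pytest.raises(ValueError):
            init_background(np.zeros((80, 4, 4), dtype=np.float32), FPS, P)

    def test_window_offsets_match_nominal_rate(self):
        assert P.bg_window_offsets(8.66) == (36, 44)

    def test_update_window_min(self):
        shape = (5, 5)
        b0 = np.full(shape, 25.0, dtype=np.float32)
        buffer = {j: np.full(shape, 25.0, dtype=np.float32) for j in range(0, 100)}
        assert np.allclose(update_background(buffer, b0, 80, FPS, P), 25.0)
        buffer[40][2, 2] = 24.0  # inside [80-44, 80-36]
        out = update_background(buffer, b0, 80, FPS, P)
        assert out[2, 2] == 24.0 and out[0, 0] == 25.0

    def test_first_frame_window_is_b0(self):
        b0 = np.full((4, 4), 23.0, dtype=np.float32)
        out = update_background({}, b0, 0, FPS, P)
        assert np.array_equal(out, b0)


class TestMouseMask:
    def test_no_warm_pixels_empty_mask(self):
        f = np.full((10, 10), 25.0, dtype=np.float32)
        m = compute_mouse_mask(f, f.copy(), full_floor((10, 10)), P)
        assert not m.any()

    def test_single_region_dilated(self):
        bg = np.full((20, 20), 25.0, dtype=np.float32)
        f = bg.copy()
        f[8:11, 8:18] = 27.0
        m = compute_mouse_mask(f, bg, full_floor((20, 20)), P)
        # oracle: dilate the warm rectangle with the exact disk footprint
        expected = np.zeros((20, 20), dtype=bool)
        expected[8:11, 8:18] = True
        fp = disk_footprint(2)
        oy, ox = np.nonzero(fp)
        acc = np.zeros_like(expected)
        for dy, dx in zip(oy - 2, ox - 2):
            acc |= np.roll(np.roll(expected, dy, 0), dx, 1)
        assert np.array_equal(m, acc)

    def test_largest_floor_overlap_wins(self):
        bg = np.full((30, 30), 25.0, dtype=np.float32)
        f = bg.copy()
        f[2:10, 2:7] = 28.0  # 40-px overlap after masking floor below
        f[20:22, 20:25] = 28.0  # 10 px
        floor = np.zeros((30, 30), dtype=bool)
        floor[0:12, 0:12] = True
        floor[20:22, 20:25] = True
        m = compute_mouse_mask(f, bg, floor, P)
        assert m[5, 4] and not m[21, 22]


class TestInpainting:
    def test_empty_mask_returns_frame(self):
        f = np.arange(16, dtype=np.float32).reshape(4, 4)
        n_prev = np.zeros((4, 4), dtype=np.float32)
        assert np.array_equal(update_inpainted(n_prev, f, np.zeros((4, 4), bool)), f)

    def test_full_mask_returns_previous(self):
        f = np.arange(16, dtype=np.float32).reshape(4, 4)
        n_prev = np.full((4, 4), 7.0, dtype=np.float32)
        assert np.array_equal(update_inpainted(n_prev, f, np.ones((4, 4), bool)),
                              n_prev)

    def test_checkerboard_blend(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(6, 6)).astype(np.float32)
        n_prev = rng.normal(size=(6, 6)).astype(np.float32)
        m = np.indices((6, 6)).sum(axis=0) % 2 == 0
        out = update_inpainted(n_prev, f, m)
        assert np.array_equal(out, n_prev * m + f * ~m)


class TestFloorMedianAndDifference:
    def test_uniform_floor(self):
        b = np.full((8, 8), 24.0, dtype=np.float32)
        none = np.zeros((8, 8), bool)
        assert compute_floor_median(b, full_floor((8, 8)), none, none) == 24.0

    def test_lower_median_with_mouse_excluded(self):
        b = np.array([[23.0, 24.0, 100.0]], dtype=np.float32)
        floor = np.ones((1, 3), bool)
        mouse = np.array([[False, False, True]])
        none = np.zeros((1, 3), bool)
        assert compute_floor_median(b, floor, mouse, none) == 23.0

    def test_mouse_covering_floor_rejected(self):
        b = np.full((4, 4), 24.0, dtype=np.float32)
        with pytest.raises(ValueError):
            compute_floor_median(b, full_floor((4, 4)), np.ones((4, 4), bool),
                                 np.zeros((4, 4), bool))

    def test_difference_pixelwise_max(self):
        f = np.array([[26.0, 26.0]], dtype=np.float32)
        b = np.array([[25.0, 23.0]], dtype=np.float32)
        d = compute_difference(f, b, 24.0)
        # where B >= T: D = F - B; where cooled urine makes B < T: D = F - T
        assert d[0, 0] == 1.0 and d[0, 1] == 2.0
        assert np.all(compute_difference(np.maximum(b, 24.0), b, 24.0) == 0.0)


class TestCooldown:
    def test_constant_pixel_zero(self):
        frames = np.full((100, 3, 3), 25.0, dtype=np.float32)
        assert np.all(compute_cooldown(frames, 10, FPS, P) == 0.0)

    def test_decaying_pixel(self):
        frames = np.full((400, 2, 2), 25.0, dtype=np.float32)
        frames[:30, 0, 0] = 36.0  # decays to 25 within the 40-s horizon
        assert compute_cooldown(frames, 10, FPS, P)[0, 0] == pytest.approx(11.0)

    def test_last_frame_zero(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(50, 4, 4)).astype(np.float32)
        assert np.all(compute_cooldown(frames, 49, FPS, P) == 0.0)

    @pytest.mark.parametrize("n,fps", [(300, 8.66), (500, 8.66), (200, 3.0)])
    def test_vectorized_equals_per_frame(self, n, fps):
        rng = np.random.default_rng(n)
        frames = (25 + rng.normal(size=(n, 6, 6))).astype(np.float32)
        all_cd = compute_cooldown_all(frames, fps, P)
        for i in range(0, n, 7):
            assert np.array_equal(all_cd[i], compute_cooldown(frames, i, fps, P))
        assert np.array_equal(all_cd[n - 1], compute_cooldown(frames, n - 1, fps, P))


class TestBlobMask:
    def _masks(self, shape=(1, 1)):
        return np.zeros(shape, bool), np.zeros(shape, bool)

    def test_included_when_all_conditions_hold(self):
        d = np.array([[2.0]], dtype=np.float32)
        cd = np.array([[1.5]], dtype=np.float32)
        m, mp = self._masks()
        assert compute_blob_mask(d, m, mp, cd, P)[0, 0]

    def test_excluded_when_cooldown_too_small(self):
        d = np.array([[2.0]], dtype=np.float32)
        cd = np.array([[1.0]], dtype=np.float32)
        m, mp = self._masks()
        assert not compute_blob_mask(d, m, mp, cd, P)[0, 0]

    def test_excluded_inside_previous_mouse_mask(self):
        d = np.array([[5.0]], dtype=np.float32)
        cd = np.array([[4.0]], dtype=np.float32)
        m = np.array([[False]])
        mp = np.array([[True]])
        assert not compute_blob_mask(d, m, mp, cd, P)[0, 0]

    def test_strict_inequalities(self):
        m, mp = self._masks()
        d = np.array([[1.6]], dtype=np.float32)
        cd = np.array([[1.6]], dtype=np.float32)
        assert not compute_blob_mask(d, m, mp, cd, P)[0, 0]  # D not > 1.6
        d = np.array([[2.0]], dtype=np.float32)
        cd = np.array([[1.0]], dtype=np.float32)
        assert not compute_blob_mask(d, m, mp, cd, P)[0, 0]  # CD not > 0.5 D


class TestRefineBlobs:
    def _refine(self, bm, floor=None):
        shape = bm.shape
        floor = full_floor(shape) if floor is None else floor
        none = np.zeros(shape, bool)
        return refine_blobs(bm, floor, none, none, P)

    def test_single_pixel_blob_discarded(self):
        bm = np.zeros((30, 30), bool)
        bm[10, 10] = True
        assert self._refine(bm) == []

    def test_size_boundary_900(self):
        bm = np.zeros((60, 60), bool)
        bm[5:35, 5:35] = True  # 900 px, stays 900 after closing
        assert len(self._refine(bm)) == 1
        bm[35, 5:35] = True  # grow one row: 930 px
        big = self._refine(bm)
        assert big == []

    def test_nearby_drops_merged_by_closing(self):
        bm = np.zeros((30, 30), bool)
        bm[9:12, 5:8] = True
        bm[9:12, 12:15] = True  # two 3x3 drops, 4-px gap bridged by disk r=4
        blobs = self._refine(bm)
        assert len(blobs) == 1
        assert blobs[0][10, 9]

    def test_blob_touching_mouse_discarded(self):
        bm = np.zeros((20, 20), bool)
        bm[5, 5:8] = True
        mouse = np.zeros((20, 20), bool)
        mouse[6, 8] = True  # diagonal neighbour of (5,7)
        assert refine_blobs(bm, full_floor((20, 20)), mouse,
                            np.zeros((20, 20), bool), P) == []

    def test_blob_leaving_floor_discarded(self):
        bm = np.zeros((20, 20), bool)
        bm[5, 5:8] = True
        floor = full_floor((20, 20))
        floor[5, 7] = False
        assert self._refine(bm, floor) == []


class TestAssociation:
    def _blob(self, where, shape=(20, 20)):
        b = np.zeros(shape, bool)
        b[where] = True
        return b

    def _track(self, blob, frame, fps=FPS):
        t = BlobTrack(track_id=0, union_mask=blob.copy())
        t.frames_detected.append(frame)
        t.peaks.append(1.0)
        t.peak_pixels.append((0, 0))
        return t

    def test_merge_within_30s(self):
        blob = self._blob((slice(5, 8), slice(5, 8)))
        tracks = [self._track(blob, 0)]
        d = np.full((20, 20), 2.0, dtype=np.float32)
        associate_blobs(tracks, [blob], d, int(10 * FPS), FPS, P)
        assert len(tracks) == 1 and len(tracks[0].frames_detected) == 2

    def test_new_track_after_31s(self):
        blob = self._blob((slice(5, 8), slice(5, 8)))
        tracks = [self._track(blob, 0)]
        d = np.full((20, 20), 2.0, dtype=np.float32)
        associate_blobs(tracks, [blob], d, int(round(31 * FPS)), FPS, P)
        assert len(tracks) == 2

    def test_disjoint_blob_new_track(self):
        tracks = [self._track(self._blob((slice(5, 8), slice(5, 8))), 0)]
        other = self._blob((slice(15, 18), slice(15, 18)))
        d = np.full((20, 20), 2.0, dtype=np.float32)
        associate_blobs(tracks, [other], d, 5, FPS, P)
        assert len(tracks) == 2

    def test_merge_into_oldest(self):
        blob = self._blob((slice(5, 8), slice(5, 8)))
        t0 = self._track(blob, 0)
        t1 = self._track(blob, 3)
        t1.track_id = 1
        tracks = [t0, t1]
        d = np.full((20, 20), 2.0, dtype=np.float32)
        associate_blobs(tracks, [blob], d, 10, FPS, P)
        assert len(t0.frames_detected) == 2 and len(t1.frames_detected) == 1


class TestFinalize:
    def test_single_frame_track_dropped(self):
        blob = np.zeros((10, 10), bool)
        blob[2, 2] = True
        t = BlobTrack(0, blob, [5], [2.0], [(2, 2)])
        assert finalize_tracks([t], P) == []

    def test_constant_intensity_selects_earliest(self):
        blob = np.zeros((10, 10), bool)
        blob[2, 2:4] = True
        t = BlobTrack(0, blob, [5, 6, 7], [2.0, 2.0, 2.0],
                      [(2, 2), (3, 2), (3, 2)])
        rec = finalize_tracks([t], P)[0]
        assert rec["selected_frame"] == 5 and (rec["x"], rec["y"]) == (2, 2)

    def test_area_scaling(self):
        blob = np.zeros((10, 10), bool)
        blob[0:5, 0:10] = True  # 50 px
        t = BlobTrack(0, blob, [1, 2], [2.0, 1.0], [(0, 0), (0, 0)])
        rec = finalize_tracks([t], P)[0]
        assert rec["area_px"] == 50
        assert rec["area_px"] * P.pixel_area_cm2 == pytest.approx(1.0)


class TestClosingHelper:
    def test_closing_is_extensive_and_idempotent(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.8
        closed = binary_close(mask, 4)
        assert (closed | mask).sum() == closed.sum()  # contains the input
        assert np.array_equal(binary_close(closed, 4), closed)


class TestEndToEnd:
    def test_event_free_session_has_no_detections(self):
        cfg = config_from_preset("easy", seed=11, habituation_s=40.0,
                                 trial_s=40.0, schedule=None)
        sim = render_session(cfg)
        video = apply_calibration(sim.video, sim.calibration)
        assert run_preliminary_detection(video, sim.annotation) == []

    def test_detections_found_near_ground_truth(self, small_session):
        sim = small_session["sim"]
        dets = run_preliminary_detection(small_session["video"], sim.annotation)
        assert len(dets) == len(sim.gt_events) == 4
        for e in sim.gt_events:
            best = min(dets, key=lambda d: np.hypot(d.x - e.x, d.y - e.y))
            assert np.hypot(best.x - e.x, best.y - e.y) <= 3.0
            assert abs(best.time_s - e.frame / sim.video.fps) <= 15.0

    def test_static_tail_does_not_change_output(self):
        # appending >40 s of static frames after the last event leaves the
        # detections unchanged (the cooldown horizon saturates)
        rng = np.random.default_rng(2)
        fps = 8.66
        n = int(60 * fps)
        frames = np.full((n, 24, 24), 25.0, dtype=np.float32)
        frames += rng.normal(scale=0.02, size=frames.shape).astype(np.float32)
        # wandering warm mouse in the top-left corner (so the mouse mask does
        # not latch onto the deposit), deposit in the lower-right
        yy, xx = np.mgrid[0:24, 0:24]
        pos = np.array([5.0, 5.0])
        for i in range(n):
            pos = np.clip(pos + rng.normal(scale=1.0, size=2), 4, 8)
            blob = np.hypot(xx - pos[0], yy - pos[1]) <= 2.5
            frames[i] = np.where(blob, 34.0, frames[i])
        t0 = int(30 * fps)
        for i in range(t0, n):
            a = (i - t0) / fps
            frames[i, 16:19, 16:19] += 9.0 * np.exp(-a / 20.0)
        floor = np.zeros((24, 24), bool)
        floor[2:22, 2:22] = True
        from thermark.predetect import run_stage

        base = run_stage(frames, fps, floor, P)
        tail = np.repeat(frames[-1:], int(45 * fps), axis=0)
        extended = run_stage(np.concatenate([frames, tail]), fps, floor, P)
        strip = lambda recs: [
            {k: v for k, v in r.items() if k != "union_mask"} for r in recs
        ]
        assert strip(base) == strip(extended)
        assert len(base) == 1
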