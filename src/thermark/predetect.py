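"""Preliminary detection of hot blobs in calibrated thermal video.

Fresh urine and fecal deposits appear at body temperature on a cooler arena
floor and cool down within tens of seconds (large urine pools take minutes),
ending up slightly darker than the dry floor.  The detector exploits both
effects: a running background image built from mouse-inpainted frames makes
new warm blobs stand out in a difference image, and a forward-looking
cooldown image rejects warm things that do not cool (the mouse, reflections).

Pipeline per frame ``i`` (habituation and trial stages are processed
independently, so small arena shifts between stages do not matter):

1. mouse mask ``M_i``: dilate ``F_i - B_(i-1)``, threshold at 1 degC, keep
   the 8-connected component with the largest arena-floor overlap;
2. inpainted frame ``N_i``: mouse pixels keep their last pre-mouse value;
3. background ``B_i``: per-pixel minimum of the inpainted frames from
   roughly 5 to 4 seconds ago (window offsets ``[4r, 5r-1]`` with
   ``r = round(fps)``; 9 frames at 8.66 fps);
4. difference ``D_i = F_i - max(T, B_i)`` with ``T`` the floor median of
   ``B_i`` (prevents extra sensitivity over dark, cooled-urine floor);
5. cooldown ``CD_i = F_i - min`` of the next 40 s of frames;
6. hot-blob mask: ``D_i > dT_threshold``, outside ``M_i`` and ``M_(i-1)``,
   ``CD_i > 1.1`` degC and ``CD_i > 0.5 * D_i`` (all strict);
7. morphological closing (disk radius 4) merges nearby droplets; blobs that
   leave the floor, touch the mouse, or have < 2 or > 900 pixels are
   discarded;
8. blobs are associated over time by mask intersection (gap <= 30 s); tracks
   seen in >= 2 frames become preliminary detections, reported at the frame
   and pixel of maximal difference intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .session_model import ArenaAnnotation, rasterize_polygon
from .thermal_io import ThermalVideo

STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def disk_footprint(radius: int) -> np.ndarray:
    """Exact Euclidean disk {p : ||p|| <= radius}."""
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx * xx + yy * yy <= r * r


@dataclass
class DetectorParams:
    dT_threshold: float = 1.6  # degC, hot-blob threshold on D
    mouse_threshold: float = 1.0  # degC, mouse-mask threshold
    mouse_dilate_radius: int = 2
    close_radius: int = 4
    min_blob_px: int = 2
    max_blob_px: int = 900
    cooldown_horizon_s: float = 40.0
    cooldown_min_C: float = 1.1
    cooldown_frac: float = 0.5
    bg_init_s: float = 20.0
    bg_window_s: tuple = (4.0, 5.0)
    assoc_max_gap_s: float = 30.0
    min_detected_frames: int = 2
    pixel_area_cm2: float = 0.02

    def __post_init__(self) -> None:
        if self.min_blob_px > self.max_blob_px:
            raise ValueError("min_blob_px must be <= max_blob_px")
        if not (0 < self.bg_window_s[0] < self.bg_window_s[1] <= self.bg_init_s):
            raise ValueError("need 0 < bg_window_s[0] < bg_window_s[1] <= bg_init_s")
        for name in (
            "dT_threshold", "mouse_threshold", "cooldown_horizon_s",
            "cooldown_min_C", "cooldown_frac", "bg_init_s", "assoc_max_gap_s",
            "pixel_area_cm2",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def bg_window_offsets(self, fps: float) -> tuple:
        """Frame offsets (hi, lo) so the window is j in [i-lo, i-hi].

        One second's worth of frames (r = round(fps)) ending 4 s back:
        offsets [4r, 5r-1]; at the nominal 8.66 fps this is [36, 44].
        """
        r = int(round(fps))
        lo = int(round(self.bg_window_s[1] * r)) - 1
        hi = int(round(self.bg_window_s[0] * r))
        return hi, lo


@dataclass
class BlobTrack:
    """A temporally associated hot blob (stage-local frame indices)."""

    track_id: int
    union_mask: np.ndarray
    frames_detected: list = field(default_factory=list)
    peaks: list = field(default_factory=list)  # per-frame max D in the blob
    peak_pixels: list = field(default_factory=list)  # (x, y) of the per-frame argmax

    @property
    def first_frame(self) -> int:
        return self.frames_detected[0]

    @property
    def last_frame(self) -> int:
        return self.frames_detected[-1]


@dataclass
class PreliminaryDetection:
    det_id: int
    stage: str
    selected_frame: int  # global frame index
    time_s: float
    x: int
    y: int
    area_px: int
    area_cm2: float
    n_frames: int
    first_frame: int
    last_frame: int
    union_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# individual stages (unit-testable; the orchestrator below uses the same code)
# ---------------------------------------------------------------------------

def init_background(frames: np.ndarray, fps: float, params: DetectorParams) -> np.ndarray:
    """Per-pixel minimum over the first ``bg_init_s`` seconds of video."""
    n_init = int(round(params.bg_init_s * fps))
    if len(frames) < n_init:
        raise ValueError(
            f"video too short: {len(frames)} frames < {n_init} needed to "
            "initialise the background"
        )
    return frames[:n_init].min(axis=0)


def compute_mouse_mask(
    frame: np.ndarray,
    bg_prev: np.ndarray,
    floor_mask: np.ndarray,
    params: DetectorParams,
) -> np.ndarray:
    """Warm connected component with the largest arena-floor overlap."""
    warm = ndimage.binary_dilation(
        (frame - bg_prev) > params.mouse_threshold,
        structure=disk_footprint(params.mouse_dilate_radius),
    )
    labels, n = ndimage.label(warm, structure=STRUCT8)
    if n == 0:
        return np.zeros_like(warm)
    overlaps = np.bincount(labels[floor_mask], minlength=n + 1)[1:]
    # ties (and the all-zero-overlap case) resolved by scan order: the
    # component whose first pixel comes earliest in row-major order
    first_px = ndimage.minimum(
        np.arange(labels.size).reshape(labels.shape), labels,
        index=np.arange(1, n + 1),
    )
    best = int(min(range(n), key=lambda k: (-overlaps[k], first_px[k]))) + 1
    return labels == best


def update_inpainted(
    n_prev: np.ndarray, frame: np.ndarray, mouse_mask: np.ndarray
) -> np.ndarray:
    return np.where(mouse_mask, n_prev, frame)


def update_background(n_buffer, b0: np.ndarray, i: int, fps: float,
                      params: DetectorParams) -> np.ndarray:
    """Per-pixel min of inpainted frames in the 5-to-4-seconds-ago window.

    ``n_buffer`` maps frame index j -> N_j; indices < 0 (or missing early
    indices) fall back to the initial background ``b0``.
    """
    hi, lo = params.bg_window_offsets(fps)
    window = [n_buffer.get(j, b0) if j >= 0 else b0 for j in range(i - lo, i - hi + 1)]
    return np.min(np.stack(window), axis=0)


def compute_floor_median(
    bg: np.ndarray,
    floor_mask: np.ndarray,
    mouse_mask: np.ndarray,
    mouse_mask_prev: np.ndarray,
) -> float:
    """Lower median of the background over mouse-free floor pixels."""
    eligible = floor_mask & ~mouse_mask & ~mouse_mask_prev
    vals = bg[eligible]
    if vals.size == 0:
        raise ValueError("no mouse-free floor pixels to take the median over")
    k = (vals.size - 1) // 2
    return float(np.partition(vals, k)[k])


def compute_difference(frame: np.ndarray, bg: np.ndarray, t_floor: float) -> np.ndarray:
    return frame - np.maximum(t_floor, bg)


def compute_cooldown(frames: np.ndarray, i: int, fps: float,
                     params: DetectorParams) -> np.ndarray:
    """F_i minus the per-pixel minimum over the next ``cooldown_horizon_s``."""
    horizon = int(round(params.cooldown_horizon_s * fps))
    return frames[i] - frames[i : min(len(frames), i + horizon + 1)].min(axis=0)


def compute_cooldown_all(frames: np.ndarray, fps: float,
                         params: DetectorParams) -> np.ndarray:
    """Cooldown image for every frame via a sliding forward minimum."""
    n = len(frames)
    horizon = int(round(params.cooldown_horizon_s * fps))
    size = horizon + 1
    if size >= n:
        rev_min = np.minimum.accumulate(frames[::-1], axis=0)[::-1]
        return frames - rev_min
    # centred min filter, shifted so window k spans [i, i + horizon]
    m = ndimage.minimum_filter1d(frames, size=size, axis=0, mode="nearest")
    s = size // 2
    fut = np.empty_like(frames)
    fut[: n - s] = m[s:]
    # near the video end the window truncates; use a reverse running minimum
    tail = np.minimum.accumulate(frames[n - size :][::-1], axis=0)[::-1]
    fut[n - s :] = tail[size - s :]
    return frames - fut


def compute_blob_mask(
    diff: np.ndarray,
    mouse_mask: np.ndarray,
    mouse_mask_prev: np.ndarray,
    cooldown: np.ndarray,
    params: DetectorParams,
) -> np.ndarray:
    return (
        (diff > params.dT_threshold)
        & ~mouse_mask
        & ~mouse_mask_prev
        & (cooldown > params.cooldown_min_C)
        & (cooldown > params.cooldown_frac * diff)
    )


def binary_close(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with an exact-disk element, computed as on an
    infinite False background (padding removes library border conventions)."""
    fp = disk_footprint(radius)
    pad = 2 * radius
    padded = np.pad(mask, pad)
    closed = ndimage.binary_erosion(ndimage.binary_dilation(padded, fp), fp)
    return closed[pad:-pad, pad:-pad]


def refine_blobs(
    blob_mask: np.ndarray,
    floor_mask: np.ndarray,
    mouse_mask: np.ndarray,
    mouse_mask_prev: np.ndarray,
    params: DetectorParams,
) -> list:
    """Close, label, and filter candidate blobs; returns boolean masks."""
    if not blob_mask.any():
        return []
    closed = binary_close(blob_mask, params.close_radius)
    labels, n = ndimage.label(closed, structure=STRUCT8)
    if n == 0:
        return []
    near_mouse = ndimage.binary_dilation(mouse_mask | mouse_mask_prev, STRUCT8)
    candidates = []
    for lab in range(1, n + 1):
        blob = labels == lab
        size = int(blob.sum())
        if size < params.min_blob_px or size > params.max_blob_px:
            continue
        if (blob & ~floor_mask).any():
            continue
        if (blob & near_mouse).any():
            continue
        candidates.append(blob)
    # deterministic processing order: first pixel in row-major scan order
    candidates.sort(key=lambda b: int(np.flatnonzero(b.ravel())[0]))
    return candidates


def associate_blobs(
    tracks: list,
    candidates: list,
    diff: np.ndarray,
    frame_i: int,
    fps: float,
    params: DetectorParams,
) -> list:
    """Merge each candidate into the oldest intersecting recent track, or
    start a new track.  Per-frame peak intensity is the max of D in the blob."""
    for blob in candidates:
        masked = np.where(blob, diff, -np.inf)
        flat = int(np.argmax(masked))  # row-major first on ties
        py, px = np.unravel_index(flat, diff.shape)
        peak = float(diff[py, px])
        matches = [
            t
            for t in tracks
            if (frame_i - t.last_frame) / fps <= params.assoc_max_gap_s
            and (t.union_mask & blob).any()
        ]
        if matches:
            target = min(matches, key=lambda t: (t.first_frame, t.track_id))
            target.union_mask |= blob
        else:
            target = BlobTrack(track_id=len(tracks), union_mask=blob.copy())
            tracks.append(target)
        target.frames_detected.append(frame_i)
        target.peaks.append(peak)
        target.peak_pixels.append((int(px), int(py)))
    return tracks


def finalize_tracks(tracks: list, params: DetectorParams) -> list:
    """Drop short tracks; pick the maximal-intensity frame and pixel.

    Returns stage-local records ``(selected_frame, x, y, area_px, n_frames,
    first_frame, last_frame, union_mask)`` ordered by first appearance.
    """
    out = []
    for t in sorted(tracks, key=lambda t: (t.first_frame, t.track_id)):
        if len(t.frames_detected) < params.min_detected_frames:
            continue
        sel = int(np.argmax(t.peaks))  # earliest on ties
        x, y = t.peak_pixels[sel]
        out.append(
            {
                "selected_frame": t.frames_detected[sel],
                "x": x,
                "y": y,
                "area_px": int(t.union_mask.sum()),
                "n_frames": len(t.frames_detected),
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
                "union_mask": t.union_mask,
            }
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def iter_frame_contexts(frames: np.ndarray, fps: float, floor_mask: np.ndarray,
                        params: DetectorParams):
    """Yield the per-frame intermediates (M, N, B, T, D, CD, BM, candidates).

    ``frames`` is one stage of calibrated video, 0-based; frame 0 already
    runs through the full pipeline against the initial background.
    """
    b0 = init_background(frames, fps, params)
    cd_all = compute_cooldown_all(frames, fps, params)
    hi, lo = params.bg_window_offsets(fps)
    n_recent: dict = {}
    b_prev = b0
    m_prev = np.zeros(frames.shape[1:], dtype=bool)
    for i in range(len(frames)):
        f = frames[i]
        m = compute_mouse_mask(f, b_prev, floor_mask, params)
        n_prev = n_recent.get(i - 1, b0)
        n_img = update_inpainted(n_prev, f, m)
        n_recent[i] = n_img
        n_recent.pop(i - lo - 1, None)  # keep exactly the window [i-lo, i]
        b = update_background(n_recent, b0, i, fps, params)
        t_floor = compute_floor_median(b, floor_mask, m, m_prev)
        d = compute_difference(f, b, t_floor)
        cd = cd_all[i]
        bm = compute_blob_mask(d, m, m_prev, cd, params)
        candidates = refine_blobs(bm, floor_mask, m, m_prev, params)
        yield {
            "i": i, "M": m, "N": n_img, "B": b, "T": t_floor, "D": d,
            "CD": cd, "BM": bm, "candidates": candidates,
        }
        b_prev = b
        m_prev = m


def run_stage(frames: np.ndarray, fps: float, floor_mask: np.ndarray,
              params: DetectorParams) -> list:
    """Run the full pipeline on one stage; returns finalize_tracks records."""
    tracks: list = []
    for ctx in iter_frame_contexts(frames, fps, floor_mask, params):
        if ctx["candidates"]:
            associate_blobs(tracks, ctx["candidates"], ctx["D"], ctx["i"], fps, params)
    return finalize_tracks(tracks, params)


def run_preliminary_detection(
    video: ThermalVideo,
    annotation: ArenaAnnotation,
    params: DetectorParams | None = None,
    keep_masks: bool = False,
) -> list:
    """Detect candidate deposition events in a calibrated session video."""
    params = params or DetectorParams()
    annotation.validate_against_video(video.n_frames)
    floor_mask = rasterize_polygon(annotation.floor_polygon, video.height, video.width)
    detections: list = []
    for stage in ("habituation", "trial"):
        first, last = annotation.stage_interval(stage)
        stage_frames = np.ascontiguousarray(
            video.frames[first : last + 1], dtype=np.float32
        )
        records = run_stage(stage_frames, video.fps, floor_mask, params)
        for rec in records:
            g = rec["selected_frame"] + first
            detections.append(
                PreliminaryDetection(
                    det_id=len(detections),
                    stage=stage,
                    selected_frame=g,
                    time_s=float(video.timestamps[g]),
                    x=rec["x"],
                    y=rec["y"],
                    area_px=rec["area_px"],
                    area_cm2=rec["area_px"] * params.pixel_area_cm2,
                    n_frames=rec["n_frames"],
                    first_frame=rec["first_frame"] + first,
                    last_frame=rec["last_frame"] + first,
                    union_mask=rec["union_mask"] if keep_masks else None,
                )
            )
    return detections


_CSV_COLUMNS = [
    "det_id", "stage", "selected_frame", "time_s", "x", "y",
    "area_px", "area_cm2", "n_frames", "first_frame", "last_frame",
]


def save_detections(detections: list, path) -> None:
    df = pd.DataFrame(
        [{c: getattr(d, c) for c in _CSV_COLUMNS} for d in detections],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_detections(path) -> list:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            PreliminaryDetection(
                det_id=int(r.det_id), stage=str(r.stage),
                selected_frame=int(r.selected_frame), time_s=float(r.time_s),
                x=int(r.x), y=int(r.y), area_px=int(r.area_px),
                area_cm2=float(r.area_cm2), n_frames=int(r.n_frames),
                first_frame=int(r.first_frame), last_frame=int(r.last_frame),
            )
        )
    return out
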