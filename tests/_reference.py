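"""Independent brute-force references used as test oracles.

These deliberately avoid the package's incremental machinery: no ring
buffers, no sliding-window filters; backgrounds and cooldowns are recomputed
from scratch per frame, morphology and labelling go through scikit-image,
and matching enumerates every ground-truth/detection pair explicitly.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as sk_label
from skimage.morphology import dilation as _sk_dilation
from skimage.morphology import erosion as _sk_erosion
from skimage.morphology import disk as sk_disk


def sk_dilate(mask, footprint):
    return _sk_dilation(mask.astype(bool), footprint).astype(bool)


def sk_erode(mask, footprint):
    return _sk_erosion(mask.astype(bool), footprint).astype(bool)


# ---------------------------------------------------------------------------
# naive Algorithm-1 reference
# ---------------------------------------------------------------------------

def naive_mouse_mask(frame, bg_prev, floor_mask, p):
    warm = sk_dilate((frame - bg_prev) > p.mouse_threshold,
                     sk_disk(p.mouse_dilate_radius))
    labels = sk_label(warm, connectivity=2)
    n = labels.max()
    if n == 0:
        return np.zeros_like(warm, dtype=bool)
    best, best_key = None, None
    for lab in range(1, n + 1):
        comp = labels == lab
        overlap = int((comp & floor_mask).sum())
        first = int(np.flatnonzero(comp.ravel())[0])
        key = (-overlap, first)
        if best_key is None or key < best_key:
            best, best_key = comp, key
    return best


def naive_close(mask, radius):
    pad = 2 * radius
    padded = np.pad(mask, pad)
    closed = sk_erode(sk_dilate(padded, sk_disk(radius)), sk_disk(radius))
    return closed[pad:-pad, pad:-pad]


def naive_candidates(bm, floor_mask, m, m_prev, p):
    if not bm.any():
        return []
    labels = sk_label(naive_close(bm, p.close_radius), connectivity=2)
    near_mouse = sk_dilate(m | m_prev, np.ones((3, 3), bool))
    blobs = []
    for lab in range(1, labels.max() + 1):
        blob = labels == lab
        size = int(blob.sum())
        if size < p.min_blob_px or size > p.max_blob_px:
            continue
        if (blob & ~floor_mask).any() or (blob & near_mouse).any():
            continue
        blobs.append(blob)
    blobs.sort(key=lambda b: int(np.flatnonzero(b.ravel())[0]))
    return blobs


def naive_stage(frames, fps, floor_mask, p):
    """Full per-frame recomputation of every Algorithm-1 intermediate.

    Returns (list of per-frame dicts, final detection records).
    """
    frames = np.asarray(frames, dtype=np.float32)
    n = len(frames)
    r = int(round(fps))
    lo = int(round(p.bg_window_s[1] * r)) - 1
    hi = int(round(p.bg_window_s[0] * r))
    n_init = int(round(p.bg_init_s * fps))
    assert n >= n_init
    b0 = frames[:n_init].min(axis=0)
    horizon = int(round(p.cooldown_horizon_s * fps))

    all_N = []
    contexts = []
    tracks = []  # dicts: mask, frames, peaks, pixels, first, id
    b_prev = b0
    m_prev = np.zeros(frames.shape[1:], dtype=bool)
    for i in range(n):
        f = frames[i]
        m = naive_mouse_mask(f, b_prev, floor_mask, p)
        n_img = np.where(m, all_N[i - 1] if i > 0 else b0, f)
        all_N.append(n_img)
        window = [all_N[j] if j >= 0 else b0 for j in range(i - lo, i - hi + 1)]
        b = np.min(np.stack(window), axis=0)
        eligible = sorted(b[floor_mask & ~m & ~m_prev].tolist())
        t_floor = float(eligible[(len(eligible) - 1) // 2])
        d = f - np.maximum(t_floor, b)
        cd = f - frames[i : min(n, i + horizon + 1)].min(axis=0)
        bm = ((d > p.dT_threshold) & ~m & ~m_prev
              & (cd > p.cooldown_min_C) & (cd > p.cooldown_frac * d))
        cands = naive_candidates(bm, floor_mask, m, m_prev, p)
        contexts.append({"i": i, "M": m, "N": n_img, "B": b, "T": t_floor,
                         "D": d, "CD": cd, "BM": bm})
        for blob in cands:
            vals = np.where(blob, d, -np.inf)
            flat = int(np.argmax(vals))
            py, px = np.unravel_index(flat, d.shape)
            hits = [t for t in tracks
                    if (i - t["frames"][-1]) / fps <= p.assoc_max_gap_s
                    and (t["mask"] & blob).any()]
            if hits:
                tgt = min(hits, key=lambda t: (t["frames"][0], t["id"]))
                tgt["mask"] = tgt["mask"] | blob
            else:
                tgt = {"id": len(tracks), "mask": blob.copy(), "frames": [],
                       "peaks": [], "pixels": []}
                tracks.append(tgt)
            tgt["frames"].append(i)
            tgt["peaks"].append(float(d[py, px]))
            tgt["pixels"].append((int(px), int(py)))
        b_prev = b
        m_prev = m

    records = []
    for t in sorted(tracks, key=lambda t: (t["frames"][0], t["id"])):
        if len(t["frames"]) < p.min_detected_frames:
            continue
        sel = int(np.argmax(t["peaks"]))
        records.append({
            "selected_frame": t["frames"][sel],
            "x": t["pixels"][sel][0],
            "y": t["pixels"][sel][1],
            "area_px": int(t["mask"].sum()),
            "n_frames": len(t["frames"]),
            "first_frame": t["frames"][0],
            "last_frame": t["frames"][-1],
            "union_mask": t["mask"],
        })
    return contexts, records


# ---------------------------------------------------------------------------
# brute-force matcher reference
# ---------------------------------------------------------------------------

def brute_force_match(gt_events, detections, max_dist=20.0, max_dt=15.0,
                      fps=8.66):
    """Exhaustive re-implementation of the matching principles; returns a
    dict with correct / misclassified / missed / false-alarm bookkeeping."""
    gt = list(gt_events)
    det = list(detections)
    taken = set()
    correct, mis, missed = [], [], []
    order = sorted(
        range(len(gt)),
        key=lambda i: (gt[i].frame / fps, gt[i].x, gt[i].y, gt[i].label),
    )
    for gi in order:
        g = gt[gi]
        gt_t = g.frame / fps
        in_window = []
        for d in det:
            if d.det_id in taken:
                continue
            dist = ((d.x - g.x) ** 2 + (d.y - g.y) ** 2) ** 0.5
            if dist <= max_dist and abs(d.time_s - gt_t) <= max_dt:
                in_window.append((dist, abs(d.time_s - gt_t), d))
        same = sorted(
            (w for w in in_window if w[2].label == g.label),
            key=lambda w: w[2].det_id,
        )
        if same:
            ids = [w[2].det_id for w in same]
            taken.update(ids)
            correct.append((gi, sorted(ids)))
        elif in_window:
            in_window.sort(key=lambda w: (w[0], w[1], w[2].det_id))
            taken.add(in_window[0][2].det_id)
            mis.append((gi, in_window[0][2].det_id))
        else:
            missed.append(gi)
    fas = sorted(d.det_id for d in det if d.det_id not in taken)
    return {"correct": correct, "misclassified": mis, "missed": missed,
            "false_alarms": fas}


def brute_force_confusion(gt_events, detections, match):
    """3x4 tally mirroring the documented confusion layout."""
    rows = {"urine": 0, "feces": 1, "BG": 2, "Miss": 3}
    cols = {"urine": 0, "feces": 1, "BG": 2, "background": 2}
    counts = np.zeros((4, 3), dtype=int)
    by_id = {d.det_id: d for d in detections}
    for gi, _ids in match["correct"]:
        lab = gt_events[gi].label
        counts[rows[lab], cols[lab]] += 1
    for gi, det_id in match["misclassified"]:
        counts[rows[gt_events[gi].label], cols[by_id[det_id].label]] += 1
    for gi in match["missed"]:
        counts[rows["Miss"], cols[gt_events[gi].label]] += 1
    for det_id in match["false_alarms"]:
        counts[rows["BG"], cols[by_id[det_id].label]] += 1
    return counts
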