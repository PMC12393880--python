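"""Accuracy evaluation with spatial/temporal matching tolerance.

A ground-truth tag is correctly detected if a detection with the same label
lies within 20 px and 15 s (both inclusive); all same-label detections in
that window are absorbed by it and are not false alarms.  If only
differently labelled detections exist in the window, the closest one
(smallest spatial distance, ties by smallest |dt|, then lowest det_id) is
recorded as the misclassification.  Ground truth is processed greedily in
order of occurrence and each detection is matched at most once; detections
left unmatched at the end are false alarms.

The confusion matrix has ground-truth rows (urine, feces, BG, Miss) and
predicted columns (urine, feces, BG): the Miss row counts tags never reached
by a preliminary detection (entered under the tag's own class column), and
the BG row counts false alarms by predicted label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEPOSIT_CLASSES = ("urine", "feces")
GT_ROWS = ("urine", "feces", "BG", "Miss")
PRED_COLS = ("urine", "feces", "BG")


@dataclass
class MatchConfig:
    max_dist_px: float = 20.0
    max_dt_s: float = 15.0

    def __post_init__(self) -> None:
        if not (self.max_dist_px > 0 and self.max_dt_s > 0):
            raise ValueError("matching tolerances must be positive")


@dataclass
class LabeledDetection:
    """A classified automatic detection on the session time base."""

    det_id: int
    label: str  # urine | feces | background
    time_s: float
    x: float
    y: float
    stage: str | None = None
    area_cm2: float = 0.0


@dataclass
class MatchResult:
    correct: list = field(default_factory=list)  # (gt_index, [det_id, ...])
    misclassified: list = field(default_factory=list)  # (gt_index, det_id)
    missed: list = field(default_factory=list)  # gt_index
    false_alarms: list = field(default_factory=list)  # det_id
    gt_events: list = field(default_factory=list)
    detections: list = field(default_factory=list)


def _det_label(det) -> str:
    return "BG" if det.label == "background" else det.label


def match_events(gt_events: list, detections: list, cfg: MatchConfig | None = None,
                 fps: float = 8.66) -> MatchResult:
    """Greedy tolerance matching of ground truth against detections.

    ``gt_events`` carry a frame index (converted to seconds via ``fps``);
    ``detections`` carry ``time_s`` directly.
    """
    cfg = cfg or MatchConfig()
    result = MatchResult(gt_events=list(gt_events), detections=list(detections))
    gt_times = [e.frame / fps for e in gt_events]
    order = sorted(
        range(len(gt_events)),
        key=lambda i: (gt_times[i], gt_events[i].x, gt_events[i].y,
                       gt_events[i].label),
    )
    consumed: set = set()
    for gi in order:
        gt = gt_events[gi]
        window = []
        for det in detections:
            if det.det_id in consumed:
                continue
            dist = float(np.hypot(det.x - gt.x, det.y - gt.y))
            dt = abs(det.time_s - gt_times[gi])
            if dist <= cfg.max_dist_px and dt <= cfg.max_dt_s:
                window.append((dist, dt, det))
        same = [w for w in window if w[2].label == gt.label]
        if same:
            ids = sorted(w[2].det_id for w in same)
            consumed.update(ids)
            result.correct.append((gi, ids))
        elif window:
            dist, dt, det = min(window, key=lambda w: (w[0], w[1], w[2].det_id))
            consumed.add(det.det_id)
            result.misclassified.append((gi, det.det_id))
        else:
            result.missed.append(gi)
    result.false_alarms = sorted(
        d.det_id for d in detections if d.det_id not in consumed
    )
    return result


@dataclass
class ConfusionMatrix:
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((len(GT_ROWS), len(PRED_COLS)), dtype=int)
    )

    def __getitem__(self, key) -> int:
        row, col = key
        return int(self.counts[GT_ROWS.index(row), PRED_COLS.index(col)])

    def add(self, row: str, col: str, n: int = 1) -> None:
        self.counts[GT_ROWS.index(row), PRED_COLS.index(col)] += n

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(GT_ROWS), columns=list(PRED_COLS))

    def gt_count(self, label: str) -> int:
        """Total ground-truth events of ``label`` accounted for anywhere."""
        row = self.counts[GT_ROWS.index(label)].sum()
        return int(row + self[("Miss", label)])


def build_confusion(match: MatchResult) -> ConfusionMatrix:
    cm = ConfusionMatrix()
    by_id = {d.det_id: d for d in match.detections}
    for gi, _ids in match.correct:
        lab = match.gt_events[gi].label
        cm.add(lab, lab)
    for gi, det_id in match.misclassified:
        cm.add(match.gt_events[gi].label, _det_label(by_id[det_id]))
    for gi in match.missed:
        cm.add("Miss", match.gt_events[gi].label)
    for det_id in match.false_alarms:
        cm.add("BG", _det_label(by_id[det_id]))
    return cm


@dataclass
class AccuracyReport:
    precision: dict
    recall: dict
    f1: dict
    mean_f1: float | None
    confusion: ConfusionMatrix | None = None
    strata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        doc = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_f1": self.mean_f1,
        }
        if self.confusion is not None:
            doc["confusion"] = {
                "rows": list(GT_ROWS),
                "cols": list(PRED_COLS),
                "counts": self.confusion.counts.tolist(),
            }
        if self.strata:
            doc["strata"] = {
                name: {k: (v.to_dict() if isinstance(v, AccuracyReport) else v)
                       for k, v in sub.items()} if isinstance(sub, dict)
                else sub.to_dict()
                for name, sub in self.strata.items()
            }
        return doc


def score_report(cm: ConfusionMatrix, skip_undefined: bool = False) -> AccuracyReport:
    """Per-class precision/recall/F1 and their mean over urine and feces.

    Zero denominators score 0; with ``skip_undefined`` a class with no
    ground-truth events gets ``None`` instead (F1 undefined), and the mean F1
    is ``None`` if either class is undefined.
    """
    precision, recall, f1 = {}, {}, {}
    for c in DEPOSIT_CLASSES:
        other = "feces" if c == "urine" else "urine"
        tp = cm[(c, c)]
        fp = cm[("BG", c)] + cm[(other, c)]
        fn = cm[("Miss", c)] + cm[(c, other)] + cm[(c, "BG")]
        if skip_undefined and cm.gt_count(c) == 0:
            precision[c] = recall[c] = f1[c] = None
            continue
        p = tp / (tp + fp) if (tp + fp) else 0.0
        r = tp / (tp + fn) if (tp + fn) else 0.0
        precision[c], recall[c] = p, r
        f1[c] = 2 * p * r / (p + r) if (p + r) else 0.0
    defined = [f1[c] for c in DEPOSIT_CLASSES if f1[c] is not None]
    mean = sum(defined) / 2 if len(defined) == 2 else None
    return AccuracyReport(precision, recall, f1, mean, confusion=cm)


def evaluate(gt_events: list, detections: list, cfg: MatchConfig | None = None,
             fps: float = 8.66) -> AccuracyReport:
    """Match, tally and score in one step."""
    return score_report(build_confusion(match_events(gt_events, detections, cfg, fps)))


# ---------------------------------------------------------------------------
# stratified reports
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    gt_events: list
    detections: list
    annotation: object
    fps: float = 8.66
    meta: dict = field(default_factory=dict)  # e.g. {"test": "SP", "sex": "male"}


STAGE_WINDOWS = {  # seconds relative to stage start
    "habituation_start": ("habituation", 0.0, 240.0),
    "habituation_end": ("habituation", 600.0, 840.0),
    "trial": ("trial", 0.0, 240.0),
}


def _stage_rel_time(annotation, fps, stage, time_s):
    first, _last = annotation.stage_interval(stage)
    return time_s - first / fps


def _filter_session(rec: SessionRecord, keep_gt, keep_det):
    gts = [e for e in rec.gt_events if keep_gt(e)]
    dets = [d for d in rec.detections if keep_det(d)]
    return gts, dets


def _pooled_report(pairs, cfg, fps_list) -> AccuracyReport:
    cm = ConfusionMatrix()
    for (gts, dets), fps in zip(pairs, fps_list):
        cm = cm + build_confusion(match_events(gts, dets, cfg, fps))
    return score_report(cm, skip_undefined=True)


def stratified_report(sessions: list, cfg: MatchConfig | None = None,
                      strata=("stage_window", "test", "sex", "floor_third")) -> dict:
    """Accuracy pooled over sessions, per stratum.

    Strata: experiment stage windows (habituation start/end, trial), test
    label and subject sex from the session metadata, and three equal-width
    divisions of the arena floor along its long axis.  A class without
    ground truth in a stratum is reported as undefined (None), not 0.
    """
    cfg = cfg or MatchConfig()
    out: dict = {}
    fps_list = [s.fps for s in sessions]
    if "stage_window" in strata:
        sub = {}
        for name, (stage, t0, t1) in STAGE_WINDOWS.items():
            pairs = []
            for rec in sessions:
                ann = rec.annotation

                def in_window_gt(e, stage=stage, t0=t0, t1=t1, rec=rec):
                    st = rec.annotation.stage_of_frame(e.frame)
                    if st != stage:
                        return False
                    t = _stage_rel_time(rec.annotation, rec.fps, st, e.frame / rec.fps)
                    return t0 <= t < t1

                def in_window_det(d, stage=stage, t0=t0, t1=t1, rec=rec):
                    if d.stage != stage:
                        return False
                    t = _stage_rel_time(rec.annotation, rec.fps, stage, d.time_s)
                    return t0 <= t < t1

                pairs.append(_filter_session(rec, in_window_gt, in_window_det))
            sub[name] = _pooled_report(pairs, cfg, fps_list)
        out["stage_window"] = sub
    for key in ("test", "sex"):
        if key not in strata:
            continue
        groups: dict = {}
        for rec in sessions:
            groups.setdefault(rec.meta.get(key, "unknown"), []).append(rec)
        out[key] = {
            val: _pooled_report(
                [(r.gt_events, r.detections) for r in recs], cfg,
                [r.fps for r in recs],
            )
            for val, recs in sorted(groups.items())
        }
    if "floor_third" in strata:
        sub = {}
        for third in range(3):
            pairs = []
            for rec in sessions:
                xs = [v[0] for v in rec.annotation.floor_polygon]
                ys = [v[1] for v in rec.annotation.floor_polygon]
                if max(xs) - min(xs) >= max(ys) - min(ys):
                    lo, hi, coord = min(xs), max(xs), lambda o: o.x
                else:
                    lo, hi, coord = min(ys), max(ys), lambda o: o.y
                edges = np.linspace(lo, hi, 4)
                a, b = edges[third], edges[third + 1]
                last = third == 2

                def inside(o, a=a, b=b, last=last, coord=coord):
                    c = coord(o)
                    return a <= c <= b if last else a <= c < b

                pairs.append(_filter_session(rec, inside, inside))
            sub[f"third_{third + 1}"] = _pooled_report(pairs, cfg, fps_list)
        out["floor_third"] = sub
    return out


def save_report(report: AccuracyReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), sort_keys=True, indent=1) + "\n")
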