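"""Deposition-dynamics summaries: per-minute rates/areas, stage windows,
percent-active subjects and side attribution.

Minute bins are half-open ``[60k, 60(k+1))`` seconds relative to stage
start.  The standard comparison windows are habituation minutes 1-4
(``[0, 240)`` s), habituation minutes 11-14 (``[600, 840)`` s), trial minute
1 (``[0, 60)``) and trial minutes 2-4 (``[60, 240)``).  The last minute of
each stage (minute 15 of habituation, minute 5 of the trial) can be excluded
because a deposit needs about a minute of subsequent video to be classified
reliably; none of the standard windows touch those minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_model import ArenaAnnotation, assign_side

LABELS = ("urine", "feces")

STAGE_WINDOWS = {
    "habituation_min_1_4": ("habituation", 0.0, 240.0),
    "habituation_min_11_14": ("habituation", 600.0, 840.0),
    "trial_min_1": ("trial", 0.0, 60.0),
    "trial_min_2_4": ("trial", 60.0, 240.0),
}


@dataclass
class DepositionEvent:
    """A classified deposition, timed relative to its stage start."""

    label: str  # urine | feces
    time_s: float
    stage: str  # habituation | trial
    x: float
    y: float
    area_cm2: float
    side: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError("label must be urine or feces")
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be positive")


def events_from_detections(classified: list, annotation: ArenaAnnotation,
                           fps: float) -> list:
    """Build deposition events from classified detections, dropping those
    labelled background and attaching the arena side."""
    events = []
    for det, label, _scores in classified:
        if label == "background":
            continue
        first, _ = annotation.stage_interval(det.stage)
        try:
            side = assign_side(det.x, det.y, annotation)
        except ValueError:
            side = None
        events.append(
            DepositionEvent(
                label=label,
                time_s=det.time_s - first / fps,
                stage=det.stage,
                x=det.x,
                y=det.y,
                area_cm2=det.area_cm2,
                side=side,
            )
        )
    return events


def per_minute_series(events: list, stage_lengths: dict) -> pd.DataFrame:
    """Event counts and deposited area per minute bin, per stage and label.

    ``stage_lengths`` maps stage name -> stage duration in seconds.
    """
    rows = []
    for stage, length in stage_lengths.items():
        n_min = int(np.ceil(length / 60.0))
        for label in LABELS:
            counts = np.zeros(n_min)
            areas = np.zeros(n_min)
            for e in events:
                if e.stage != stage or e.label != label:
                    continue
                k = int(e.time_s // 60)
                if 0 <= k < n_min:
                    counts[k] += 1
                    areas[k] += e.area_cm2
            for k in range(n_min):
                rows.append(
                    {"stage": stage, "minute": k + 1, "label": label,
                     "rate_per_min": counts[k], "area_cm2_per_min": areas[k]}
                )
    return pd.DataFrame(rows, columns=["stage", "minute", "label",
                                       "rate_per_min", "area_cm2_per_min"])


_EXCLUDED = {"habituation": (840.0, 900.0), "trial": (240.0, 300.0)}


@dataclass
class StageSummary:
    rates: dict  # (label, window) -> events/min
    areas: dict  # (label, window) -> cm^2/min
    active: dict  # label -> bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": lab, "window": win, "rate_per_min": self.rates[(lab, win)],
             "area_cm2_per_min": self.areas[(lab, win)], "active": self.active[lab]}
            for lab in LABELS
            for win in STAGE_WINDOWS
        ]
        return pd.DataFrame(rows)


def stage_summary(events: list, include_last_minute: bool = True) -> StageSummary:
    """Mean rate and area over the standard stage windows; a subject is
    *active* for a label if it has at least one such event in the session."""
    kept = events
    if not include_last_minute:
        kept = [
            e for e in events
            if not (_EXCLUDED[e.stage][0] <= e.time_s < _EXCLUDED[e.stage][1])
        ]
    rates, areas = {}, {}
    for label in LABELS:
        for win, (stage, t0, t1) in STAGE_WINDOWS.items():
            sel = [e for e in kept
                   if e.label == label and e.stage == stage and t0 <= e.time_s < t1]
            minutes = (t1 - t0) / 60.0
            rates[(label, win)] = len(sel) / minutes
            areas[(label, win)] = sum(e.area_cm2 for e in sel) / minutes
    active = {label: any(e.label == label for e in events) for label in LABELS}
    return StageSummary(rates, areas, active)


def side_attribution(events: list, annotation: ArenaAnnotation) -> dict:
    """Per-side event counts per label, and the fraction of events deposited
    on the preferred-stimulus side (None when no preference is annotated)."""
    counts: dict = {}
    for e in events:
        side = e.side if e.side is not None else assign_side(e.x, e.y, annotation)
        counts.setdefault(e.label, {}).setdefault(side, 0)
        counts[e.label][side] += 1
    out = {"per_side": counts, "preferred_side": annotation.preferred_side}
    fractions = {}
    for label in LABELS:
        per = counts.get(label, {})
        total = sum(per.values())
        if annotation.preferred_side is None or total == 0:
            fractions[label] = None
        else:
            fractions[label] = per.get(annotation.preferred_side, 0) / total
        out.setdefault("totals", {})[label] = total
    out["preferred_fraction"] = fractions
    return out


def summary_frame(events: list, include_last_minute: bool = True) -> pd.DataFrame:
    return stage_summary(events, include_last_minute).to_frame()


def cohort_summary(summaries: list) -> pd.DataFrame:
    """Aggregate per-subject stage summaries: mean rate and area per window
    and the percentage of active subjects per label."""
    rows = []
    for label in LABELS:
        active = [s.active[label] for s in summaries]
        for win in STAGE_WINDOWS:
            rows.append({
                "label": label,
                "window": win,
                "mean_rate_per_min": float(np.mean(
                    [s.rates[(label, win)] for s in summaries])),
                "mean_area_cm2_per_min": float(np.mean(
                    [s.areas[(label, win)] for s in summaries])),
                "pct_active": 100.0 * float(np.mean(active)),
                "n_subjects": len(summaries),
            })
    return pd.DataFrame(rows)
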