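"""Manual session inputs: arena geometry, stage intervals, ground truth.

Conventions used throughout the package: coordinates are 0-based with
``x`` = column and ``y`` = row, origin at the top-left pixel centre; frame
intervals are closed ``[first, last]``.  The arena is split into two halves
by the midline perpendicular to the long axis of the floor polygon's
bounding box (the stimulus chambers sit at opposite corners); a point
exactly on the midline belongs to the first-listed ("left") side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely import contains_xy

STAGES = ("habituation", "trial")


def _check_polygon(vertices) -> Polygon:
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    poly = Polygon([(float(x), float(y)) for x, y in vertices])
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("polygon must be simple and non-degenerate")
    return poly


@dataclass
class ArenaAnnotation:
    """Arena-floor polygon, blackbody region, stage intervals, side map."""

    floor_polygon: list  # [(x, y), ...]
    blackbody_polygon: list
    habituation_interval: tuple  # (first_frame, last_frame), closed
    trial_interval: tuple
    side_map: dict = field(default_factory=dict)  # {"left": label, "right": label}
    preferred_side: str | None = None

    def __post_init__(self) -> None:
        _check_polygon(self.floor_polygon)
        _check_polygon(self.blackbody_polygon)
        self.floor_polygon = [(float(x), float(y)) for x, y in self.floor_polygon]
        self.blackbody_polygon = [
            (float(x), float(y)) for x, y in self.blackbody_polygon
        ]
        self.habituation_interval = tuple(int(v) for v in self.habituation_interval)
        self.trial_interval = tuple(int(v) for v in self.trial_interval)
        for first, last in (self.habituation_interval, self.trial_interval):
            if first < 0 or last < first:
                raise ValueError("stage intervals must satisfy 0 <= first <= last")
        if self.trial_interval[0] <= self.habituation_interval[1]:
            raise ValueError("habituation must end before the trial starts")
        if self.side_map and set(self.side_map) != {"left", "right"}:
            raise ValueError("side_map keys must be exactly {'left', 'right'}")
        if self.preferred_side is not None and self.side_map:
            if self.preferred_side not in self.side_map.values():
                raise ValueError("preferred_side must be one of the side labels")

    def stage_interval(self, stage: str) -> tuple:
        if stage == "habituation":
            return self.habituation_interval
        if stage == "trial":
            return self.trial_interval
        raise ValueError(f"unknown stage {stage!r}")

    def stage_of_frame(self, frame: int) -> str | None:
        for stage in STAGES:
            first, last = self.stage_interval(stage)
            if first <= frame <= last:
                return stage
        return None

    def validate_against_video(self, n_frames: int) -> None:
        if self.trial_interval[1] >= n_frames:
            raise ValueError("stage intervals exceed video length")


@dataclass
class GroundTruthEvent:
    """A single manual click: deposit label, first clearly visible frame, pixel."""

    label: str  # "urine" | "feces"
    frame: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.label not in ("urine", "feces"):
            raise ValueError("label must be 'urine' or 'feces'")
        self.frame = int(self.frame)


def save_annotation(annotation: ArenaAnnotation, path) -> None:
    doc = {
        "floor_polygon": [list(v) for v in annotation.floor_polygon],
        "blackbody_polygon": [list(v) for v in annotation.blackbody_polygon],
        "habituation_interval": list(annotation.habituation_interval),
        "trial_interval": list(annotation.trial_interval),
        "side_map": annotation.side_map,
        "preferred_side": annotation.preferred_side,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_annotation(path) -> ArenaAnnotation:
    doc = json.loads(Path(path).read_text())
    try:
        return ArenaAnnotation(
            floor_polygon=[tuple(v) for v in doc["floor_polygon"]],
            blackbody_polygon=[tuple(v) for v in doc["blackbody_polygon"]],
            habituation_interval=tuple(doc["habituation_interval"]),
            trial_interval=tuple(doc["trial_interval"]),
            side_map=dict(doc.get("side_map") or {}),
            preferred_side=doc.get("preferred_side"),
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"annotation JSON missing field {exc}") from exc


def save_ground_truth(events, path) -> None:
    df = pd.DataFrame(
        [{"label": e.label, "frame": e.frame, "x": e.x, "y": e.y} for e in events],
        columns=["label", "frame", "x", "y"],
    )
    df.to_csv(path, index=False)


def load_ground_truth(path) -> list:
    df = pd.read_csv(path)
    return [
        GroundTruthEvent(r.label, int(r.frame), float(r.x), float(r.y))
        for r in df.itertuples()
    ]


def rasterize_polygon(polygon, height: int, width: int) -> np.ndarray:
    """Boolean mask: pixel (row y, col x) is true iff its centre (x, y) lies
    strictly inside the polygon (even-odd rule; simple polygons only)."""
    poly = _check_polygon(polygon)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height))
    mask = contains_xy(poly, xs.ravel().astype(float), ys.ravel().astype(float))
    return mask.reshape(height, width)


def _long_axis_and_mid(annotation: ArenaAnnotation):
    xs = [v[0] for v in annotation.floor_polygon]
    ys = [v[1] for v in annotation.floor_polygon]
    wx, wy = max(xs) - min(xs), max(ys) - min(ys)
    if wx >= wy:
        return 0, (max(xs) + min(xs)) / 2.0
    return 1, (max(ys) + min(ys)) / 2.0


def assign_side(x: float, y: float, annotation: ArenaAnnotation) -> str:
    """Stimulus label of the arena half containing (x, y).

    Halves are delimited by the midline perpendicular to the floor bounding
    box's long axis; the "left" side is the lower-coordinate half along that
    axis and also receives midline points (tie rule).
    """
    poly = _check_polygon(annotation.floor_polygon)
    if not (contains_xy(poly, x, y) or poly.boundary.distance(Point(x, y)) == 0):
        raise ValueError(f"point ({x}, {y}) is outside the arena floor")
    axis, mid = _long_axis_and_mid(annotation)
    coord = x if axis == 0 else y
    key = "left" if coord <= mid else "right"
    if not annotation.side_map:
        return key
    return annotation.side_map[key]
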