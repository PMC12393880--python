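"""Synthetic thermal sessions with exact ground truth.

The generator emulates the phenomenology the detector relies on: a warm
mouse-shaped blob performing a reflecting random walk on a cooler floor,
deposition events that appear near body temperature and decay exponentially
toward a slightly *below*-floor asymptote (fresh deposits read warm, cooled
deposits read dark), per-pixel fixed-pattern non-uniformity, global sensor
drift cancelled by a constant 37 degC blackbody patch, and iid Gaussian
sensor noise.  A deposit at time ``t0`` adds, inside its disk,

    peak_dT * exp(-(t-t0)/tau) - dark_offset * (1 - exp(-(t-t0)/tau))

to the local floor temperature, scaled by a mild radial profile (the centre
stays warmest) so the representative pixel is well defined.  Everything is
drawn from one seeded generator; a fixed seed reproduces the session
byte-identically.

Presets (``easy``, ``occlusion``, ``dense``) are YAML files shipped with the
package; ``config_from_preset`` samples an explicit event schedule from the
preset's ranges.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .session_model import ArenaAnnotation, GroundTruthEvent
from .thermal_io import CalibrationBundle, ThermalVideo

STAGES = ("habituation", "trial")


@dataclass
class SimEvent:
    stage: str
    time_s: float  # relative to stage start
    x: int
    y: int
    label: str  # urine | feces
    radius_px: float
    peak_dT_C: float
    tau_s: float
    dark_offset_C: float = 0.5


@dataclass
class SimConfig:
    width: int = 384
    height: int = 288
    fps: float = 8.66
    habituation_s: float = 900.0
    trial_s: float = 300.0
    gap_s: float = 0.0
    floor_temp_C: float = 25.0
    floor_sigma_C: float = 0.3  # spatial, static
    wall_temp_C: float = 22.0
    mouse_temp_C: float = 35.0
    mouse_radius_px: float = 7.0
    mouse_edge_sigma_px: float = 1.5
    step_sigma_px: float = 1.8
    dwell_prob: float = 0.05
    events: list = field(default_factory=list)
    noise_sigma_C: float = 0.05
    nuc_amp_C: float = 0.3
    blackbody_temp_C: float = 37.0
    drift_amp_C: float = 0.3
    drift_period_s: float = 120.0
    event_center_bias: float = 0.15  # radial falloff of the deposit profile
    avoid_events: str = "always"  # always | window | never
    clearance_px: float = 20.0
    clearance_before_s: float = 10.0
    clearance_after_s: float = 45.0
    dwell_at_events: bool = False  # occlusion mode: park on deposit sites
    floor_polygon: list | None = None
    blackbody_polygon: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_polygon is None or self.blackbody_polygon is None:
            floor, bb = default_geometry(self.width, self.height)
            self.floor_polygon = self.floor_polygon or floor
            self.blackbody_polygon = self.blackbody_polygon or bb
        for e in self.events:
            if e.stage not in STAGES:
                raise ValueError(f"unknown stage {e.stage!r}")
            if e.tau_s <= 0:
                raise ValueError("event tau must be positive")
            dur = self.habituation_s if e.stage == "habituation" else self.trial_s
            if not 0 <= e.time_s < dur:
                raise ValueError("event time outside its stage")
            xs = [v[0] for v in self.floor_polygon]
            ys = [v[1] for v in self.floor_polygon]
            if not (min(xs) < e.x < max(xs) and min(ys) < e.y < max(ys)):
                raise ValueError("event position outside the arena floor")

    def stage_frames(self) -> dict:
        n_hab = int(round(self.habituation_s * self.fps))
        n_gap = int(round(self.gap_s * self.fps))
        n_trial = int(round(self.trial_s * self.fps))
        return {
            "habituation": (0, n_hab - 1),
            "trial": (n_hab + n_gap, n_hab + n_gap + n_trial - 1),
            "n_total": n_hab + n_gap + n_trial,
        }


def default_geometry(width: int, height: int):
    """Rectangular floor with a blackbody patch in the spare top-left margin."""
    bb = max(4, min(10, width // 16))
    left = bb + 2 * 2 + 2  # blackbody column + margins
    floor = [
        (left - 0.5, 5.5),
        (width - 6.5, 5.5),
        (width - 6.5, height - 6.5),
        (left - 0.5, height - 6.5),
    ]
    blackbody = [
        (1.5, 1.5),
        (1.5 + bb, 1.5),
        (1.5 + bb, 1.5 + bb),
        (1.5, 1.5 + bb),
    ]
    return floor, blackbody


@dataclass
class SimOutput:
    video: ThermalVideo  # uncalibrated (NUC + drift + noise applied)
    calibration: CalibrationBundle
    annotation: ArenaAnnotation
    gt_events: list
    clean_frames: np.ndarray | None = None  # noiseless, calibrated scene


def _event_global_time(cfg: SimConfig, e: SimEvent) -> float:
    if e.stage == "habituation":
        return e.time_s
    return cfg.habituation_s + cfg.gap_s + e.time_s


def _floor_bounds(cfg: SimConfig):
    xs = [v[0] for v in cfg.floor_polygon]
    ys = [v[1] for v in cfg.floor_polygon]
    return min(xs), max(xs), min(ys), max(ys)


def simulate_trajectory(cfg: SimConfig, rng) -> np.ndarray:
    """Per-frame mouse centre: reflecting random walk on the floor.

    Depending on ``avoid_events`` the walk rejects steps entering the
    clearance disk around each deposit site (always, only in a window around
    the deposition time, or never); with ``dwell_at_events`` the mouse
    instead parks on upcoming deposit sites to create occlusions.
    """
    n = cfg.stage_frames()["n_total"]
    x0, x1, y0, y1 = _floor_bounds(cfg)
    r = cfg.mouse_radius_px
    lo = np.array([x0 + r + 1, y0 + r + 1])
    hi = np.array([x1 - r - 1, y1 - r - 1])
    excl_r = cfg.clearance_px + cfg.mouse_radius_px
    sites = np.array([[e.x, e.y] for e in cfg.events]).reshape(-1, 2)
    times = np.array([_event_global_time(cfg, e) for e in cfg.events])

    def active_sites(t: float):
        if cfg.avoid_events == "never" or len(sites) == 0:
            return sites[:0]
        if cfg.avoid_events == "always":
            return sites
        sel = (times - cfg.clearance_before_s <= t) & (
            t <= times + cfg.clearance_after_s
        )
        return sites[sel]

    def ok(pos, t):
        act = active_sites(t)
        return len(act) == 0 or np.all(
            np.hypot(act[:, 0] - pos[0], act[:, 1] - pos[1]) >= excl_r
        )

    # start at the reachable point farthest from any deposit site
    gx = np.linspace(lo[0], hi[0], 9)
    gy = np.linspace(lo[1], hi[1], 9)
    grid = np.array([[x, y] for x in gx for y in gy])
    if len(sites):
        dmin = np.array(
            [np.hypot(sites[:, 0] - c[0], sites[:, 1] - c[1]).min() for c in grid]
        )
        pos = grid[int(np.argmax(dmin))].astype(float)
    else:
        pos = grid[0].astype(float)
    out = np.empty((n, 2))
    dwell_target = None
    for i in range(n):
        t = i / cfg.fps
        if cfg.dwell_at_events and len(sites):
            upcoming = (times - 5.0 <= t) & (t <= times + 20.0)
            dwell_target = sites[upcoming][0] if upcoming.any() else None
        if dwell_target is not None:
            pos = pos + np.clip(dwell_target - pos, -3.0, 3.0)
        elif cfg.step_sigma_px > 0 and not (rng.uniform() < cfg.dwell_prob):
            for _ in range(100):
                step = rng.normal(scale=cfg.step_sigma_px, size=2)
                cand = pos + step
                # reflect off the floor boundary
                for k in range(2):
                    if cand[k] < lo[k]:
                        cand[k] = 2 * lo[k] - cand[k]
                    elif cand[k] > hi[k]:
                        cand[k] = 2 * hi[k] - cand[k]
                cand = np.clip(cand, lo, hi)
                if ok(cand, t):
                    pos = cand
                    break
        else:
            # consume a draw so dwell/no-dwell paths stay reproducible
            rng.uniform()
        out[i] = pos
    return out


def _event_profile(e: SimEvent, cfg: SimConfig):
    """(local disk weights, slices) for stamping the event into a frame."""
    r = e.radius_px
    ri = int(np.ceil(r))
    yy, xx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
    d = np.hypot(xx, yy)
    w = np.where(d <= r, 1.0 - cfg.event_center_bias * (d / max(r, 1e-9)) ** 2, 0.0)
    return w, ri


def render_session(cfg: SimConfig, return_clean: bool = False) -> SimOutput:
    """Render a full session and its calibration bundle / annotation / truth."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    frames_info = cfg.stage_frames()
    n = frames_info["n_total"]

    from .session_model import rasterize_polygon  # local import to avoid cycle

    floor_mask = rasterize_polygon(cfg.floor_polygon, h, w)
    bb_mask = rasterize_polygon(cfg.blackbody_polygon, h, w)

    # static scene: walls, floor with smooth spatial texture, blackbody patch
    base = np.full((h, w), cfg.wall_temp_C)
    texture = rng.normal(size=(h, w))
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(texture, sigma=6.0)
    sd = texture.std()
    if sd > 0:
        texture *= cfg.floor_sigma_C / sd
    base[floor_mask] = cfg.floor_temp_C + texture[floor_mask]
    base[bb_mask] = cfg.blackbody_temp_C

    nuc = rng.normal(scale=cfg.nuc_amp_C, size=(h, w))
    nuc -= nuc.mean()

    traj = simulate_trajectory(cfg, rng)

    events = sorted(cfg.events, key=lambda e: (_event_global_time(cfg, e), e.x, e.y))
    ev_t0 = [_event_global_time(cfg, e) for e in events]
    profiles = [_event_profile(e, cfg) for e in events]

    mr = int(np.ceil(cfg.mouse_radius_px + 4 * cfg.mouse_edge_sigma_px))
    myy, mxx = np.mgrid[-mr : mr + 1, -mr : mr + 1]

    frames = np.empty((n, h, w), dtype=np.float32)
    clean = np.empty((n, h, w), dtype=np.float32) if return_clean else None
    for i in range(n):
        t = i / cfg.fps
        scene = base.copy()
        for e, t0, (prof, ri) in zip(events, ev_t0, profiles):
            a = t - t0
            if a < 0:
                continue
            decay = np.exp(-a / e.tau_s)
            delta = e.peak_dT_C * decay - e.dark_offset_C * (1.0 - decay)
            ys = slice(max(e.y - ri, 0), min(e.y + ri + 1, h))
            xs = slice(max(e.x - ri, 0), min(e.x + ri + 1, w))
            py = slice(ys.start - (e.y - ri), ys.stop - (e.y - ri))
            px = slice(xs.start - (e.x - ri), xs.stop - (e.x - ri))
            scene[ys, xs] += delta * prof[py, px]
        # mouse: soft-edged warm disk, blended by maximum
        cx, cy = traj[i]
        ix, iy = int(round(cx)), int(round(cy))
        ys = slice(max(iy - mr, 0), min(iy + mr + 1, h))
        xs = slice(max(ix - mr, 0), min(ix + mr + 1, w))
        dy = myy[ys.start - (iy - mr) : ys.stop - (iy - mr),
                 xs.start - (ix - mr) : xs.stop - (ix - mr)] + (iy - cy)
        dx = mxx[ys.start - (iy - mr) : ys.stop - (iy - mr),
                 xs.start - (ix - mr) : xs.stop - (ix - mr)] + (ix - cx)
        d = np.hypot(dx, dy)
        rim = np.exp(-0.5 * ((d - cfg.mouse_radius_px) / cfg.mouse_edge_sigma_px) ** 2)
        weight = np.where(d <= cfg.mouse_radius_px, 1.0, rim)
        mouse = scene[ys, xs] * (1 - weight) + cfg.mouse_temp_C * weight
        scene[ys, xs] = np.maximum(scene[ys, xs], mouse)
        if return_clean:
            clean[i] = scene
        drift = cfg.drift_amp_C * np.sin(2 * np.pi * t / cfg.drift_period_s)
        noisy = scene + drift + nuc
        if cfg.noise_sigma_C > 0:
            noisy = noisy + rng.normal(scale=cfg.noise_sigma_C, size=(h, w))
        frames[i] = noisy

    video = ThermalVideo(frames, fps=cfg.fps)
    calib = CalibrationBundle(nuc, bb_mask, cfg.blackbody_temp_C)
    annotation = ArenaAnnotation(
        floor_polygon=list(cfg.floor_polygon),
        blackbody_polygon=list(cfg.blackbody_polygon),
        habituation_interval=frames_info["habituation"],
        trial_interval=frames_info["trial"],
        side_map={"left": "stim_a", "right": "stim_b"},
        preferred_side="stim_a",
    )
    gt = []
    for e, t0 in zip(events, ev_t0):
        gt.append(GroundTruthEvent(e.label, int(round(t0 * cfg.fps)), e.x, e.y))
    return SimOutput(video, calib, annotation, gt, clean_frames=clean)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def load_preset(name_or_path) -> dict:
    p = Path(str(name_or_path))
    if p.suffix in (".yaml", ".yml") and p.exists():
        return yaml.safe_load(p.read_text())
    ref = importlib.resources.files("thermark") / "presets" / f"{name_or_path}.yaml"
    return yaml.safe_load(ref.read_text())


def _jittered_grid(n: int, x0, x1, y0, y1, min_sep: float, jitter: float, rng):
    """n positions with guaranteed pairwise separation: random cells of a
    regular grid whose spacing exceeds min_sep + 2*jitter, jittered."""
    need = min_sep + 2 * jitter
    nx = max(1, int((x1 - x0) // need) + 1)
    ny = max(1, int((y1 - y0) // need) + 1)
    if nx * ny < n:
        raise ValueError(
            f"cannot place {n} events with separation {min_sep} px on this floor"
        )
    gx = np.linspace(x0, x1, nx)
    gy = np.linspace(y0, y1, ny)
    cells = [(x, y) for x in gx for y in gy]
    chosen = rng.choice(len(cells), size=n, replace=False)
    out = []
    for c in chosen:
        x, y = cells[int(c)]
        out.append(
            (
                int(round(x + rng.uniform(-jitter, jitter))),
                int(round(y + rng.uniform(-jitter, jitter))),
            )
        )
    return out


def sample_schedule(spec: dict, cfg: SimConfig, rng) -> list:
    """Draw an explicit event list from a preset's schedule ranges: positions
    spread over the floor with a guaranteed minimum pairwise separation and a
    boundary inset, times uniform in the stated range, stages round-robin."""
    x0, x1, y0, y1 = _floor_bounds(cfg)
    min_sep = float(spec.get("min_separation_px", 35.0))
    t_lo, t_hi = spec.get("time_range_s", [25.0, 75.0])
    plan = []
    for label in ("urine", "feces"):
        n_label = int(spec.get(f"n_{label}", 0))
        start = 0 if label == "urine" else 1
        for j in range(n_label):
            stage = STAGES[(start + j) % 2]
            plan.append((label, stage))
    radii = {
        label: _pair(spec[label]["radius_px"]) for label in ("urine", "feces")
        if label in spec
    }
    inset = max((r[1] for r in radii.values()), default=5.0) + 3.0
    positions = _jittered_grid(
        len(plan), x0 + inset, x1 - inset, y0 + inset, y1 - inset,
        min_sep, jitter=3.0, rng=rng,
    )
    events = []
    for (label, stage), (x, y) in zip(plan, positions):
        ranges = spec[label]
        events.append(
            SimEvent(
                stage=stage,
                time_s=float(rng.uniform(t_lo, t_hi)),
                x=x,
                y=y,
                label=label,
                radius_px=float(rng.uniform(*_pair(ranges["radius_px"]))),
                peak_dT_C=float(rng.uniform(*_pair(ranges["peak_dT_C"]))),
                tau_s=float(rng.uniform(*_pair(ranges["tau_s"]))),
                dark_offset_C=float(ranges.get("dark_offset_C", 0.5)),
            )
        )
    return events


def _pair(v):
    if isinstance(v, (int, float)):
        return float(v), float(v)
    return float(v[0]), float(v[1])


def config_from_preset(name_or_path, seed: int = 0, **overrides) -> SimConfig:
    """Build a SimConfig from a preset; the seed drives both the schedule
    sampling and the rendering."""
    doc = load_preset(name_or_path)
    doc.update(overrides)
    schedule_spec = doc.pop("schedule", None)
    doc["seed"] = seed
    cfg = SimConfig(**{k: v for k, v in doc.items() if k != "events"})
    if schedule_spec:
        rng = np.random.default_rng([seed, 1])
        events = sample_schedule(schedule_spec, cfg, rng)
        cfg = replace(cfg, events=events)
    return cfg
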