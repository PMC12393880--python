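import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from thermark import (
    ClassifierConfig,
    apply_calibration,
    augment_example,
    build_training_set,
    config_from_preset,
    materialize_example,
    render_session,
    run_preliminary_detection,
    train_classifier,
)
from thermark.depoclassify import TrainingSchedule

EASY_TRAIN_SEEDS = list(range(101, 121))  # 20 training sessions
EASY_TEST_SEEDS = list(range(201, 206))  # 5 held-out sessions


def random_algo_video(seed: int, fps: float, n_frames: int = 300, size: int = 24):
    """Small random thermal clip for implementation-vs-reference checks:
    textured floor, a wandering warm blob, two decaying step events, noise."""
    rng = np.random.default_rng(seed)
    base = 24.0 + gaussian_filter(rng.normal(size=(size, size)), 2.0) * 0.6
    frames = np.repeat(base[None], n_frames, axis=0)

    yy, xx = np.mgrid[0:size, 0:size]
    pos = np.array([size / 2, size / 2], dtype=float)
    for i in range(n_frames):
        pos = np.clip(pos + rng.normal(scale=1.2, size=2), 3, size - 4)
        d = np.hypot(xx - pos[0], yy - pos[1])
        blob = np.where(d <= 2.5, 34.0, base)
        frames[i] = np.maximum(frames[i], blob)

    for _ in range(2):
        ex, ey = rng.integers(4, size - 4, size=2)
        et = int(rng.integers(int(5 * fps), int(n_frames - 10 * fps)))
        tau = float(rng.uniform(10.0, 25.0))
        peak = float(rng.uniform(6.0, 10.0))
        d = np.hypot(xx - ex, yy - ey)
        disk = d <= 2.0
        for i in range(et, n_frames):
            a = (i - et) / fps
            delta = peak * np.exp(-a / tau) - 0.5 * (1 - np.exp(-a / tau))
            frames[i] = np.where(disk, frames[i] + delta, frames[i])

    frames = frames + rng.normal(scale=0.15, size=frames.shape)
    floor = np.zeros((size, size), dtype=bool)
    floor[2 : size - 2, 2 : size - 2] = True
    return frames.astype(np.float32), floor


def process_easy_session(seed: int, config: ClassifierConfig,
                         with_examples: bool = True, params=None):
    """Simulate one 'easy' session, detect, and optionally build materialized
    training examples; the video is dropped before returning."""
    cfg = config_from_preset("easy", seed=seed)
    sim = render_session(cfg)
    video = apply_calibration(sim.video, sim.calibration)
    detections = run_preliminary_detection(video, sim.annotation, params)
    out = {
        "seed": seed,
        "fps": cfg.fps,
        "gt": sim.gt_events,
        "annotation": sim.annotation,
        "detections": detections,
        "sim_config": cfg,
    }
    if with_examples:
        vid = f"easy-{seed}"
        examples = build_training_set(
            {vid: video}, {vid: sim.annotation}, {vid: sim.gt_events},
            {vid: detections}, seed=seed,
        )
        rng = np.random.default_rng(seed + 7)
        expanded = []
        for ex in examples:
            expanded.append(ex)
            if ex.provenance == "manual_positive":
                for _ in range(2):
                    expanded.append(augment_example(ex, rng, fps=cfg.fps))
        out["examples"] = [
            materialize_example(video, ex, config) for ex in expanded
        ]
    return out


@pytest.fixture(scope="session")
def classifier_config():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def train_data(classifier_config):
    return [process_easy_session(s, classifier_config) for s in EASY_TRAIN_SEEDS]


@pytest.fixture(scope="session")
def trained_model(train_data, classifier_config):
    examples = [ex for sess in train_data for ex in sess["examples"]]
    schedule = TrainingSchedule(epochs=20, lr_backbone=1e-3, lr_rest=1e-3,
                                drop_after=15)
    return train_classifier(examples, classifier_config, schedule, seed=0)


@pytest.fixture(scope="session")
def small_session():
    """One short easy-style session shared by integration-level tests."""
    cfg = config_from_preset(
        "easy", seed=42, habituation_s=80.0, trial_s=80.0,
        schedule={
            "n_urine": 2, "n_feces": 2,
            "time_range_s": [25.0, 33.0], "min_separation_px": 30.0,
            "urine": {"radius_px": [3.0, 5.0], "peak_dT_C": [9.0, 11.0],
                      "tau_s": [35.0, 55.0], "dark_offset_C": 0.5},
            "feces": {"radius_px": [1.2, 2.0], "peak_dT_C": [9.0, 11.0],
                      "tau_s": [30.0, 60.0], "dark_offset_C": 0.5},
        },
    )
    sim = render_session(cfg)
    video = apply_calibration(sim.video, sim.calibration)
    return {"cfg": cfg, "sim": sim, "video": video}
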