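"""Classification of preliminary detections from spatio-temporal patches.

Each candidate deposition is described by 78 grayscale 65x65 patches cropped
around its representative pixel from frames ``i + 8k``, ``k in [-12..65]``
(about -11 s to +60 s at 8.66 fps): long enough to see the deposit cool
down, be moved by the mouse, or smear.  Temperatures are mapped linearly to
grey levels (10 degC -> 0, 40 degC -> 255, clipped); frames outside the
video and pixels outside the image are padded with a uniform 22 degC
(grey level 102.0).

Consecutive patch triples form 26 three-channel tokens.  A small trainable
backbone embeds each token; a sinusoidal (x, y, t) encoding (128 dims per
axis, concatenated and affinely mapped 384 -> 256) is added; a single
learned query attends over the 26 tokens and a linear head produces scores
for urine / feces / background.  The model is implemented in NumPy with
analytic gradients and Adam, and is exactly reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .session_model import ArenaAnnotation, GroundTruthEvent, rasterize_polygon
from .thermal_io import ThermalVideo

CLASSES = ("urine", "feces", "background")


@dataclass
class ClassifierConfig:
    backbone: str = "tiny"
    coord_embed_dim: int = 128  # per axis
    joint_embed_dim: int = 256
    n_queries: int = 1
    n_classes: int = 3
    patch_px: int = 65
    frame_stride: int = 8
    k_start: int = -12
    k_stop: int = 65  # inclusive
    pad_temp_C: float = 22.0
    norm_range_C: tuple = (10.0, 40.0)
    pool_block: int = 5  # tiny backbone: 65 -> 13 block-mean pooling
    pos_scale_px: tuple = (384.0, 288.0)  # x, y normalised to [0, 2*pi]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone != "tiny":
            raise ValueError(f"unsupported backbone {self.backbone!r}")
        if self.n_queries != 1:
            raise ValueError("the classifier uses a single query")
        n = self.n_patches
        if n % 3 != 0:
            raise ValueError("number of patches must be divisible by 3")
        if self.patch_px % self.pool_block != 0:
            raise ValueError("patch_px must be divisible by pool_block")

    @property
    def k_range(self) -> range:
        return range(self.k_start, self.k_stop + 1)

    @property
    def n_patches(self) -> int:
        return self.k_stop - self.k_start + 1

    @property
    def n_tokens(self) -> int:
        return self.n_patches // 3

    @property
    def pad_value(self) -> float:
        return float(self.normalize(np.float64(self.pad_temp_C)))

    def normalize(self, temps):
        lo, hi = self.norm_range_C
        return np.clip((np.asarray(temps, dtype=np.float64) - lo) / (hi - lo) * 255.0,
                       0.0, 255.0)


@dataclass
class PatchSequence:
    patches: np.ndarray  # (n_patches, patch_px, patch_px) float32 in [0, 255]
    anchor: tuple  # (x, y, frame)
    valid_flags: np.ndarray  # (n_patches,) bool; False where padded


def extract_patch_sequence(video: ThermalVideo, x: int, y: int, frame_i: int,
                           config: ClassifierConfig | None = None) -> PatchSequence:
    """Normalized patch sequence centred at (x, y) around ``frame_i``."""
    config = config or ClassifierConfig()
    x, y = int(x), int(y)
    if not (0 <= x < video.width and 0 <= y < video.height):
        raise ValueError(f"anchor ({x}, {y}) outside the image")
    p = config.patch_px
    half = p // 2
    pad_val = config.pad_value
    patches = np.full((config.n_patches, p, p), pad_val, dtype=np.float32)
    valid = np.zeros(config.n_patches, dtype=bool)
    y0, y1 = y - half, y + half + 1
    x0, x1 = x - half, x + half + 1
    sy0, sy1 = max(y0, 0), min(y1, video.height)
    sx0, sx1 = max(x0, 0), min(x1, video.width)
    for j, k in enumerate(config.k_range):
        idx = frame_i + k * config.frame_stride
        if idx < 0 or idx >= video.n_frames:
            continue
        patch = np.full((p, p), config.pad_temp_C, dtype=np.float64)
        patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = video.frames[
            idx, sy0:sy1, sx0:sx1
        ]
        patches[j] = config.normalize(patch)
        valid[j] = True
    return PatchSequence(patches, (x, y, int(frame_i)), valid)


def pack_triples(seq: PatchSequence | np.ndarray) -> np.ndarray:
    """(3n, H, W) patches -> (n, H, W, 3) tokens; channels in temporal order."""
    patches = seq.patches if isinstance(seq, PatchSequence) else np.asarray(seq)
    n = patches.shape[0]
    if n % 3 != 0:
        raise ValueError("patch count must be divisible by 3")
    return patches.reshape(n // 3, 3, *patches.shape[1:]).transpose(0, 2, 3, 1)


def unpack_triples(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    return images.transpose(0, 3, 1, 2).reshape(-1, *images.shape[1:3])


def sinusoidal_encoding(pos: float, dim: int = 128) -> np.ndarray:
    """Standard sin/cos positional code with temperature 10000."""
    half = dim // 2
    freq = 1.0 / (10000.0 ** (np.arange(half, dtype=np.float64) / half))
    ang = float(pos) * freq
    return np.concatenate([np.sin(ang), np.cos(ang)])


def position_time_encoding(x_idx: float, y_idx: float, t_idx: float, weights,
                           config: ClassifierConfig | None = None) -> np.ndarray:
    """(x, y, t) sinusoids (128 each, same form for t as for a spatial axis),
    concatenated to 384 and affinely mapped to 256.

    Coordinates are normalised to [0, 2*pi] over the nominal frame size (and
    the token range for t) before encoding, the usual detection-transformer
    convention, so the code varies smoothly across the arena.
    """
    config = config or ClassifierConfig()
    phi = _raw_xyt_encoding(x_idx, y_idx, config.n_tokens,
                            config.coord_embed_dim, config, t_idx=t_idx)[0]
    enc_w, enc_b = (weights["enc_W"], weights["enc_b"]) if isinstance(weights, dict) \
        else weights
    return phi @ enc_w + enc_b


def _raw_xyt_encoding(x: float, y: float, n_tokens: int, d: int,
                      config: ClassifierConfig, t_idx=None) -> np.ndarray:
    """(n_tokens, 3d) concatenated sinusoids; t is the token index."""
    sx, sy = config.pos_scale_px
    two_pi = 2 * np.pi
    ex = sinusoidal_encoding(two_pi * x / sx, d)
    ey = sinusoidal_encoding(two_pi * y / sy, d)
    ts = range(n_tokens) if t_idx is None else [t_idx]
    out = np.empty((len(ts), 3 * d))
    for row, t in enumerate(ts):
        et = sinusoidal_encoding(two_pi * t / n_tokens, d)
        out[row] = np.concatenate([ex, ey, et])
    return out


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

@dataclass
class TrainingExample:
    label: str  # urine | feces | background
    provenance: str  # manual_positive | random_negative | hard_negative
    video_id: str
    anchor: tuple  # (x, y, frame)
    sequence: PatchSequence | None = None
    features: np.ndarray | None = None  # (n_tokens, feat_dim) cached tokens
    flip_h: bool = False
    flip_v: bool = False
    rot_k: int = 0  # number of 90-degree rotations

    def __post_init__(self) -> None:
        negative = self.provenance in ("random_negative", "hard_negative")
        if (self.label == "background") != negative:
            raise ValueError("background label iff negative provenance")


def is_close(x_d: float, y_d: float, t_d: float,
             x_m: float, y_m: float, t_m: float) -> bool:
    """Closeness rule for negative sampling: a candidate at (x_d, t_d) is too
    close to a manual tag at (x_m, t_m) if it is within 25 px and its time is
    between 10 s before and 30 s after the tag."""
    dist = float(np.hypot(x_d - x_m, y_d - y_m))
    return dist < 25.0 and -10.0 <= (t_d - t_m) <= 30.0


RANDOM_NEGATIVES_PER_VIDEO = 40  # half habituation, half trial
NEGATIVE_RETRY_BUDGET = 1000


def build_training_set(videos: dict, annotations: dict, gt_events: dict,
                       prelim_detections: dict, seed: int) -> list:
    """Positives at manual tags, 40 random floor negatives per video (20 per
    stage, resampled while close to a tag), and every preliminary detection
    not close to a tag as a hard negative."""
    rng = np.random.default_rng(seed)
    examples: list = []
    for vid in sorted(videos):
        video: ThermalVideo = videos[vid]
        ann: ArenaAnnotation = annotations[vid]
        events = gt_events.get(vid, [])
        tags = [(e.x, e.y, video.timestamps[e.frame]) for e in events]

        def close_to_tag(x, y, frame):
            t = video.timestamps[int(frame)]
            return any(is_close(x, y, t, xm, ym, tm) for xm, ym, tm in tags)

        for e in events:
            examples.append(TrainingExample(e.label, "manual_positive", vid,
                                            (int(e.x), int(e.y), e.frame)))
        floor = rasterize_polygon(ann.floor_polygon, video.height, video.width)
        fy, fx = np.nonzero(floor)
        per_stage = RANDOM_NEGATIVES_PER_VIDEO // 2
        for stage in ("habituation", "trial"):
            first, last = ann.stage_interval(stage)
            for _ in range(per_stage):
                for _attempt in range(NEGATIVE_RETRY_BUDGET):
                    j = int(rng.integers(len(fx)))
                    frame = int(rng.integers(first, last + 1))
                    x, y = int(fx[j]), int(fy[j])
                    if not close_to_tag(x, y, frame):
                        break
                else:
                    raise RuntimeError(
                        "could not place a random negative away from manual tags"
                    )
                examples.append(TrainingExample("background", "random_negative",
                                                vid, (x, y, frame)))
        for det in prelim_detections.get(vid, []):
            if not close_to_tag(det.x, det.y, det.selected_frame):
                examples.append(TrainingExample(
                    "background", "hard_negative", vid,
                    (int(det.x), int(det.y), int(det.selected_frame)),
                ))
    return examples


def augment_example(example: TrainingExample, rng=None, *,
                    time_shift_s: float | None = None,
                    shift: tuple | None = None,
                    flip_h: bool | None = None,
                    flip_v: bool | None = None,
                    rot_k: int | None = None,
                    fps: float = 8.66) -> TrainingExample:
    """Augmented copy: positives get an anchor time shift drawn from
    [-3 s, +6 s]; all examples a spatial shift in {-2..2}^2, optional
    horizontal/vertical flips and a rotation in {0, 90, 180, 270} degrees.
    The label is preserved.  Unspecified parameters are drawn from ``rng``.
    """
    if rng is None:
        needed = [shift, flip_h, flip_v, rot_k]
        if example.provenance == "manual_positive":
            needed.append(time_shift_s)
        if any(v is None for v in needed):
            raise ValueError("provide rng or explicit augmentation parameters")
        rng = np.random.default_rng(0)
    if time_shift_s is None:
        time_shift_s = float(rng.uniform(-3.0, 6.0)) \
            if example.provenance == "manual_positive" else 0.0
    if shift is None:
        shift = (int(rng.integers(-2, 3)), int(rng.integers(-2, 3)))
    if flip_h is None:
        flip_h = bool(rng.integers(2))
    if flip_v is None:
        flip_v = bool(rng.integers(2))
    if rot_k is None:
        rot_k = int(rng.integers(4))
    x, y, frame = example.anchor
    new_anchor = (x + int(shift[0]), y + int(shift[1]),
                  frame + int(round(time_shift_s * fps)))
    seq = example.sequence
    if seq is not None:
        patches = seq.patches
        if shift != (0, 0):
            # translate patch content; the 2-px border revealed by the shift
            # is filled by edge replication
            dx, dy = int(shift[0]), int(shift[1])
            m = max(abs(dx), abs(dy))
            if m:
                p = patches.shape[-1]
                padded = np.pad(patches, ((0, 0), (m, m), (m, m)), mode="edge")
                patches = padded[:, m + dy : m + dy + p, m + dx : m + dx + p]
        if flip_h:
            patches = patches[:, :, ::-1]
        if flip_v:
            patches = patches[:, ::-1, :]
        if rot_k % 4:
            patches = np.rot90(patches, k=rot_k % 4, axes=(1, 2))
        seq = PatchSequence(np.ascontiguousarray(patches), new_anchor,
                            seq.valid_flags.copy())
    return replace(
        example,
        anchor=new_anchor,
        sequence=seq,
        features=None,
        flip_h=example.flip_h ^ bool(flip_h),
        flip_v=example.flip_v ^ bool(flip_v),
        rot_k=(example.rot_k + int(rot_k)) % 4,
    )


def materialize_example(video: ThermalVideo, example: TrainingExample,
                        config: ClassifierConfig) -> TrainingExample:
    """Extract the patch sequence at the example's anchor (applying any
    recorded flip/rotation) and cache the backbone input tokens."""
    x, y, frame = example.anchor
    seq = extract_patch_sequence(video, x, y, frame, config)
    patches = seq.patches
    if example.flip_h:
        patches = patches[:, :, ::-1]
    if example.flip_v:
        patches = patches[:, ::-1, :]
    if example.rot_k % 4:
        patches = np.rot90(patches, k=example.rot_k % 4, axes=(1, 2))
    seq = PatchSequence(np.ascontiguousarray(patches), seq.anchor, seq.valid_flags)
    feats = _token_features(seq, config)
    return replace(example, sequence=None, features=feats)


def _token_features(seq: PatchSequence, config: ClassifierConfig) -> np.ndarray:
    """Tiny backbone input: block-mean pooled triples, scaled to [0, 1]."""
    tokens = pack_triples(seq)  # (n, p, p, 3)
    n, p, _, _ = tokens.shape
    b = config.pool_block
    g = p // b
    pooled = tokens.reshape(n, g, b, g, b, 3).mean(axis=(2, 4))  # (n, g, g, 3)
    return (pooled.reshape(n, -1) / 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainingSchedule:
    epochs: int = 40
    lr_backbone: float = 1e-3
    lr_rest: float = 1e-3
    drop_after: int | None = None
    drop_factor: float = 10.0
    batch_size: int = 16


# the reference two-round schedule used for full-scale training
ROUND1 = TrainingSchedule(epochs=230, lr_backbone=1e-5, lr_rest=1e-4,
                          drop_after=200, drop_factor=10.0)
ROUND2 = TrainingSchedule(epochs=50, lr_backbone=1e-5, lr_rest=1e-4,
                          drop_after=40, drop_factor=10.0)


class DepositClassifier:
    """Single-query attention classifier over 26 patch-triple tokens."""

    BACKBONE_KEYS = ("W_b", "b_b")

    def __init__(self, config: ClassifierConfig, params: dict, card: dict):
        self.config = config
        self.params = params
        self.card = card

    # -- forward ------------------------------------------------------------
    def _forward(self, X: np.ndarray, Phi: np.ndarray, want_cache: bool = False):
        P = self.params
        if "feat_mu" in P:  # per-feature standardisation fitted at train time
            X = (X - P["feat_mu"]) / P["feat_sd"]
        B, n, f = X.shape
        d = P["W_b"].shape[1]
        # flatten batch/token axes so the big products hit BLAS
        pre = (X.reshape(B * n, f) @ P["W_b"] + P["b_b"]).reshape(B, n, d)
        e = Phi.reshape(B * n, -1) @ P["enc_W"] + P["enc_b"]
        h = np.maximum(pre, 0.0) + e.reshape(B, n, d)  # (B, n, d)
        s = h @ P["q"] / np.sqrt(d)  # (B, n)
        s = s - s.max(axis=1, keepdims=True)
        a = np.exp(s)
        a /= a.sum(axis=1, keepdims=True)
        pooled = (a[:, None, :] @ h)[:, 0, :]  # (B, d)
        logits = pooled @ P["W_h"] + P["b_h"]
        if want_cache:
            return logits, {"X": X, "Phi": Phi, "pre": pre, "h": h, "a": a,
                            "pooled": pooled}
        return logits

    def predict_proba(self, X: np.ndarray, Phi: np.ndarray) -> np.ndarray:
        logits = self._forward(X, Phi)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def encode_inputs(self, examples_or_seqs) -> tuple:
        cfg = self.config
        X, Phi = [], []
        for item in examples_or_seqs:
            if isinstance(item, PatchSequence):
                feats = _token_features(item, cfg)
                x, y, _ = item.anchor
            else:
                if item.features is None:
                    raise ValueError("example not materialized")
                feats = item.features
                x, y, _ = item.anchor
            X.append(feats)
            Phi.append(_raw_xyt_encoding(x, y, cfg.n_tokens,
                                         cfg.coord_embed_dim, cfg))
        return (np.stack(X).astype(np.float32),
                np.stack(Phi).astype(np.float32))


def _init_params(config: ClassifierConfig, in_dim: int, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    d = config.joint_embed_dim
    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, size=shape)
    params = {
        "W_b": glorot((in_dim, d)),
        "b_b": np.zeros(d),
        # zero-initialised so the model starts content-only and recruits the
        # position/time code only where it helps generalisation
        "enc_W": np.zeros((3 * config.coord_embed_dim, d)),
        "enc_b": np.zeros(d),
        "q": rng.normal(scale=1.0 / np.sqrt(d), size=d),
        "W_h": glorot((d, config.n_classes)),
        "b_h": np.zeros(config.n_classes),
    }
    return {k: v.astype(np.float32) for k, v in params.items()}


def _grads(model: DepositClassifier, X, Phi, y_onehot, sample_w):
    logits, c = model._forward(X, Phi, want_cache=True)
    B = X.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    loss = float(-(sample_w * (y_onehot * np.log(p + 1e-12)).sum(axis=1)).sum()
                 / sample_w.sum())
    dlogits = (p - y_onehot) * (sample_w / sample_w.sum())[:, None]
    P = model.params
    g = {}
    g["W_h"] = c["pooled"].T @ dlogits
    g["b_h"] = dlogits.sum(axis=0)
    dpooled = dlogits @ P["W_h"].T  # (B, d)
    # attention backward
    a, h = c["a"], c["h"]
    B, n, d = h.shape
    dh = a[:, :, None] * dpooled[:, None, :]
    da = (h @ dpooled[:, :, None])[:, :, 0]  # (B, n)
    ds = a * (da - (a * da).sum(axis=1, keepdims=True))
    tau = 1.0 / np.sqrt(d)
    g["q"] = (ds.reshape(1, B * n) @ h.reshape(B * n, d))[0] * tau
    dh += ds[:, :, None] * (P["q"] * tau)[None, None, :]
    dh2 = dh.reshape(B * n, d)
    g["enc_W"] = c["Phi"].reshape(B * n, -1).T @ dh2
    g["enc_b"] = dh2.sum(axis=0)
    dpre = (dh * (c["pre"] > 0)).reshape(B * n, d)
    g["W_b"] = c["X"].reshape(B * n, -1).T @ dpre
    g["b_b"] = dpre.sum(axis=0)
    return loss, g


def train_classifier(examples: list, config: ClassifierConfig | None = None,
                     schedule=None, seed: int = 0) -> DepositClassifier:
    """Train on materialized examples with Adam and class-balanced
    cross-entropy.  ``schedule`` is one :class:`TrainingSchedule` or a list
    (consecutive rounds); defaults to a single desk-scale round."""
    config = config or ClassifierConfig()
    schedules = schedule if isinstance(schedule, (list, tuple)) else \
        [schedule or TrainingSchedule()]
    labels = np.array([CLASSES.index(e.label) for e in examples])
    counts = np.bincount(labels, minlength=len(CLASSES))
    if (counts == 0).any():
        missing = [c for c, n in zip(CLASSES, counts) if n == 0]
        raise ValueError(f"training set is missing class(es): {missing}")
    in_dim = examples[0].features.shape[1]
    model = DepositClassifier(config, _init_params(config, in_dim, seed), card={})
    X, Phi = model.encode_inputs(examples)
    # centre per feature, scale by one global std: keeps the relative
    # magnitude of informative vs noise-only dimensions
    flat = X.reshape(-1, in_dim)
    model.params["feat_mu"] = flat.mean(axis=0, dtype=np.float64).astype(np.float32)
    model.params["feat_sd"] = np.full(
        in_dim, max(float(flat.astype(np.float64).std()), 1e-3), dtype=np.float32
    )
    y_onehot = np.eye(len(CLASSES))[labels]
    class_w = len(labels) / (len(CLASSES) * counts.astype(float))
    sample_w = class_w[labels]

    rng = np.random.default_rng(seed + 1)
    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    history = []
    for sched in schedules:
        for epoch in range(sched.epochs):
            drop = (sched.drop_after is not None and epoch >= sched.drop_after)
            scale = (1.0 / sched.drop_factor) if drop else 1.0
            order = rng.permutation(len(labels))
            for start in range(0, len(labels), sched.batch_size):
                idx = order[start : start + sched.batch_size]
                loss, g = _grads(model, X[idx], Phi[idx], y_onehot[idx],
                                 sample_w[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                step += 1
                for k, grad in g.items():
                    lr = sched.lr_backbone if k in DepositClassifier.BACKBONE_KEYS \
                        else sched.lr_rest
                    lr *= scale
                    mstate[k] = 0.9 * mstate[k] + 0.1 * grad
                    vstate[k] = 0.999 * vstate[k] + 0.001 * grad * grad
                    mhat = mstate[k] / (1 - 0.9 ** step)
                    vhat = vstate[k] / (1 - 0.999 ** step)
                    model.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            full_loss, _ = _grads(model, X, Phi, y_onehot, sample_w)
            history.append(full_loss)
    model.card = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "schedules": [vars(s) for s in schedules],
        "seed": seed,
        "classes": list(CLASSES),
        "n_examples": len(examples),
        "final_loss": history[-1] if history else None,
        "loss_history": history,
    }
    return model


def classify_detection(model: DepositClassifier, seq: PatchSequence):
    """(label, scores) for one patch sequence; scores sum to 1."""
    X, Phi = model.encode_inputs([seq])
    probs = model.predict_proba(X, Phi)[0]
    label = CLASSES[int(np.argmax(probs))]
    return label, {c: float(p) for c, p in zip(CLASSES, probs)}


def classify_detections(model: DepositClassifier, video: ThermalVideo,
                        detections: list,
                        config: ClassifierConfig | None = None) -> list:
    """Classify each preliminary detection; returns (detection, label, scores)."""
    config = config or model.config
    out = []
    for det in detections:
        seq = extract_patch_sequence(video, det.x, det.y, det.selected_frame, config)
        label, scores = classify_detection(model, seq)
        out.append((det, label, scores))
    return out


def save_model(model: DepositClassifier, path) -> None:
    path = Path(path)
    np.savez(path, **model.params)
    card_path = path.with_suffix(".card.json")
    card_path.write_text(json.dumps(model.card, sort_keys=True, indent=1) + "\n")


def load_model(path) -> DepositClassifier:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        params = {k: z[k] for k in z.files}
    card = json.loads(path.with_suffix(".card.json").read_text())
    cfg_doc = dict(card["config"])
    cfg_doc["norm_range_C"] = tuple(cfg_doc["norm_range_C"])
    config = ClassifierConfig(**cfg_doc)
    return DepositClassifier(config, params, card)
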