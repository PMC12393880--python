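"""Radiometric thermal-video container and calibration.

A session is stored as one multi-frame 16-bit grayscale TIFF plus a JSON
sidecar (``<stem>.meta.json``) holding ``{scale, offset, fps, timestamps?,
width, height, n_frames}``.  Temperatures are reconstructed as
``T(degC) = raw * scale + offset`` (defaults ``scale=0.01``, ``offset=0``),
so the container quantisation step is 0.01 degC.

Calibration removes two sensor effects:

* fixed-pattern non-uniformity, estimated from frames of a uniform surface
  (the zero-mean *NUC image* is subtracted from every frame), and
* slow global drift of the apparent temperature, cancelled per frame using a
  constant-temperature blackbody in the field of view (default setpoint
  37 degC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

DEFAULT_SCALE = 0.01
DEFAULT_OFFSET = 0.0
DEFAULT_BLACKBODY_C = 37.0


@dataclass
class ThermalVideo:
    """Time-ordered per-pixel temperature frames (degC)."""

    frames: np.ndarray  # (n, H, W) float
    fps: float
    timestamps: np.ndarray | None = None  # seconds, per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.dtype not in (np.float32, np.float64):
            self.frames = self.frames.astype(np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames), dtype=np.float64) / self.fps
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
            if self.timestamps.shape != (len(self.frames),):
                raise ValueError("timestamps must have one entry per frame")
            if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class CalibrationBundle:
    """Per-pixel NUC offset (zero mean), blackbody mask and setpoint."""

    nuc_image: np.ndarray  # (H, W) degC
    blackbody_mask: np.ndarray  # (H, W) bool
    blackbody_setpoint: float = DEFAULT_BLACKBODY_C

    def __post_init__(self) -> None:
        self.nuc_image = np.asarray(self.nuc_image, dtype=np.float64)
        self.blackbody_mask = np.asarray(self.blackbody_mask, dtype=bool)
        if self.nuc_image.shape != self.blackbody_mask.shape:
            raise ValueError("nuc_image and blackbody_mask shapes differ")
        if abs(float(self.nuc_image.mean())) >= 1e-9:
            raise ValueError("nuc_image must have zero mean")
        if not self.blackbody_mask.any():
            raise ValueError("blackbody_mask must contain at least one pixel")


def compute_nuc_image(uniform_frames) -> np.ndarray:
    """Non-uniformity image from frames of a uniform surface.

    The frames are averaged and the average's scalar mean subtracted, giving
    a zero-mean per-pixel offset map.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in uniform_frames]
    if len(frames) == 0:
        raise ValueError("need at least one uniform frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("uniform frames have mismatched shapes")
    mean = np.mean(np.stack(frames), axis=0)
    return mean - mean.mean()


def apply_calibration(
    video: ThermalVideo,
    calib: CalibrationBundle,
    per_frame: bool = True,
) -> ThermalVideo:
    """Subtract the NUC image, then cancel blackbody drift.

    The drift offset is ``mean(frame[blackbody]) - setpoint`` computed after
    NUC subtraction; with ``per_frame=True`` (default) it is computed and
    subtracted frame by frame, which cancels slow drift; otherwise a single
    session-wide offset (mean over all frames) is used.
    """
    if calib.nuc_image.shape != video.frames.shape[1:]:
        raise ValueError("calibration shape does not match video frames")
    # arithmetic in the video's own precision (float32 videos stay float32)
    dtype = video.frames.dtype
    frames = video.frames - calib.nuc_image[None, :, :].astype(dtype)
    bb = calib.blackbody_mask
    bb_means = frames[:, bb].mean(axis=1, dtype=np.float64)
    if per_frame:
        offsets = bb_means - calib.blackbody_setpoint
    else:
        offsets = np.full(len(frames), bb_means.mean() - calib.blackbody_setpoint)
    frames = frames - offsets[:, None, None].astype(dtype)
    return ThermalVideo(frames, fps=video.fps, timestamps=video.timestamps.copy())


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def save_video(video: ThermalVideo, path) -> None:
    """Write the TIFF + sidecar container (quantisation step 0.01 degC)."""
    path = Path(path)
    scale = DEFAULT_SCALE
    # offset chosen so every temperature fits the 16-bit raw range
    offset = float(np.floor(video.frames.min()))
    raw = np.round((video.frames.astype(np.float64) - offset) / scale)
    if raw.min() < 0 or raw.max() > 65535:
        raise ValueError("temperature range not representable in 16-bit container")
    tifffile.imwrite(path, raw.astype(np.uint16))
    meta = {
        "scale": scale,
        "offset": offset,
        "fps": video.fps,
        "timestamps": [float(t) for t in video.timestamps],
        "width": video.width,
        "height": video.height,
        "n_frames": video.n_frames,
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))


def load_video(path) -> ThermalVideo:
    """Read the TIFF + sidecar container back into a :class:`ThermalVideo`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    scale = float(meta.get("scale", DEFAULT_SCALE))
    offset = float(meta.get("offset", DEFAULT_OFFSET))
    n = int(meta["n_frames"]) if "n_frames" in meta else raw.shape[0]
    if raw.shape[0] != n:
        raise ValueError(
            f"container holds {raw.shape[0]} frames, sidecar declares {n}"
        )
    if raw.shape[1:] != (int(meta["height"]), int(meta["width"])):
        raise ValueError("container frame shape disagrees with sidecar")
    frames = raw.astype(np.float64) * scale + offset
    fps = float(meta["fps"])
    ts = meta.get("timestamps")
    timestamps = np.asarray(ts, dtype=np.float64) if ts is not None else None
    return ThermalVideo(frames, fps=fps, timestamps=timestamps)


def save_calibration(calib: CalibrationBundle, directory) -> None:
    """Store a bundle as NUC TIFF + mask PNG + JSON in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "nuc.tif", calib.nuc_image.astype(np.float32))
    iio.imwrite(
        directory / "blackbody_mask.png",
        (calib.blackbody_mask.astype(np.uint8) * 255),
    )
    (directory / "calibration.json").write_text(
        json.dumps({"blackbody_setpoint": calib.blackbody_setpoint}, sort_keys=True)
    )


def load_calibration(directory) -> CalibrationBundle:
    directory = Path(directory)
    nuc = tifffile.imread(directory / "nuc.tif").astype(np.float64)
    mask = iio.imread(directory / "blackbody_mask.png") > 0
    meta = json.loads((directory / "calibration.json").read_text())
    # re-centre against float32 storage round-off
    nuc = nuc - nuc.mean()
    return CalibrationBundle(nuc, mask, float(meta["blackbody_setpoint"]))
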