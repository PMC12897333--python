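"""Readers/writers for the pipeline's standard formats.

Internal boxes are 0-based float xyxy (half-open); YOLO label files use
the ecosystem's normalized `class cx cy w h` row format.  Detections
travel as JSONL (one record per box), window series as CSV, and run
configuration as schema-checked YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection import Box, Detection

log = logging.getLogger("splashquant")


# ---------------------------------------------------------------------------
# YOLO labels
# ---------------------------------------------------------------------------

def yolo_to_xyxy(cx: float, cy: float, w: float, h: float,
                 image_size: tuple) -> Box:
    iw, ih = image_size
    return Box((cx - w / 2) * iw, (cy - h / 2) * ih,
               (cx + w / 2) * iw, (cy + h / 2) * ih)


def xyxy_to_yolo(b: Box, image_size: tuple) -> tuple:
    iw, ih = image_size
    return ((b.x_min + b.x_max) / 2 / iw, (b.y_min + b.y_max) / 2 / ih,
            (b.x_max - b.x_min) / iw, (b.y_max - b.y_min) / ih)


def read_yolo_labels(path, image_size: tuple) -> list:
    """Label file -> list of (class_id, Box).  Empty file = background image."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = map(float, parts[1:])
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: malformed row ({e})") from None
        if not (0 <= cx <= 1 and 0 <= cy <= 1 and 0 < w <= 1 and 0 < h <= 1):
            raise ValueError(f"{path}:{ln}: normalized coords out of range")
        out.append((cls, yolo_to_xyxy(cx, cy, w, h, image_size)))
    return out


def write_yolo_labels(path, entries: list, image_size: tuple) -> None:
    lines = []
    for cls, box in entries:
        cx, cy, w, h = xyxy_to_yolo(box, image_size)
        lines.append(f"{cls} {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# JSONL detections
# ---------------------------------------------------------------------------

def write_detections_jsonl(path, detections: dict) -> None:
    """detections: image_id -> list[Detection].

    Frames without detections are preserved with an explicit empty-frame
    marker so calm windows survive the round trip.
    """
    with open(path, "w") as fh:
        for image_id in detections:
            if not detections[image_id]:
                fh.write(json.dumps({"image_id": image_id, "empty": True}) + "\n")
            for d in detections[image_id]:
                fh.write(json.dumps({
                    "image_id": image_id,
                    "x_min": d.box.x_min, "y_min": d.box.y_min,
                    "x_max": d.box.x_max, "y_max": d.box.y_max,
                    "score": d.score, "class_id": d.class_id,
                }) + "\n")


def read_detections_jsonl(path) -> dict:
    out: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            r = json.loads(line)
            if r.get("empty"):
                out.setdefault(r["image_id"], [])
                continue
            det = Detection(Box(r["x_min"], r["y_min"], r["x_max"], r["y_max"]),
                            float(r["score"]), int(r.get("class_id", 0)))
        except (KeyError, ValueError, json.JSONDecodeError) as e:
            raise ValueError(f"{path}:{ln}: malformed record ({e})") from None
        out.setdefault(r["image_id"], []).append(det)
    return out


# ---------------------------------------------------------------------------
# dataset manifest / splits
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    splits: dict                 # split name -> list of (image, label) paths
    class_names: list = field(default_factory=lambda: ["splash"])

    def __post_init__(self):
        seen: set = set()
        for name, pairs in self.splits.items():
            for img, lab in pairs:
                if img in seen:
                    raise ValueError(f"image {img} appears in multiple splits")
                seen.add(img)
                if lab is None:
                    raise ValueError(f"image {img} lacks a label file")

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.splits.items()}


def split_by_session(sessions: list, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> dict:
    """Split whole sessions (clip = the basic unit) into train/val/test,
    avoiding frame-level leakage between splits."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sessions))
    n = len(sessions)
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    idx = {"train": order[:n_train],
           "val": order[n_train:n_train + n_val],
           "test": order[n_train + n_val:]}
    return {k: [sessions[i] for i in v] for k, v in idx.items()}


# ---------------------------------------------------------------------------
# frame sampling
# ---------------------------------------------------------------------------

def sample_frames(video_path, out_dir, rate_hz: float = 1.0,
                  native_fps: float | None = None) -> list:
    """Sample frames from a multi-frame container at rate_hz.

    Works with any container imageio can decode (GIF/TIFF always; MP4
    only when an ffmpeg plugin is available).  Frames are written as
    PNGs named by timestamp; returns the written paths.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        frames = iio.imread(video_path, index=None)
    except Exception as e:
        raise IOError(f"cannot decode {video_path}: {e}") from None
    if frames.ndim == 3 and frames.shape[-1] in (3, 4):
        frames = frames[None]
    n = len(frames)
    if native_fps is None:
        meta = iio.immeta(video_path)
        native_fps = float(meta.get("fps", 0) or 0)
        if not native_fps:
            dur = meta.get("duration", 0)  # per-frame duration, ms (GIF)
            native_fps = 1000.0 / dur if dur else 30.0
    if rate_hz > native_fps + 1e-9:
        raise ValueError(f"rate {rate_hz} Hz exceeds native fps {native_fps}")
    step = native_fps / rate_hz
    written = []
    k = 0
    while True:
        i = int(round(k * step))
        if i >= n:
            break
        ts = i / native_fps
        p = out_dir / f"t{ts:010.3f}.png"
        iio.imwrite(p, frames[i])
        written.append(p)
        k += 1
    return written


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "model", "weights", "thresholds", "controller", "session", "grader",
    "seed", "log_level", "window_s", "conf_threshold", "nms_iou",
}


def load_run_config(path) -> dict:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True,
    )
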