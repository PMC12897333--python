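"""Synthetic feeding sessions: detection streams and rendered scenes.

Real feeding footage shows a characteristic stage-wise evolution —
rapid rise of splash activity after feed delivery, a sustained
high-intensity plateau, then gradual decay back to a calm surface.  The
generator encodes that as a piecewise activity profile a(t) in [0, 1]
(calm / rise / plateau / decay / tail) driving

  * per-window splash counts ~ Poisson(lambda_max * a(t)),
  * log-normal splash areas,
  * a texture-energy stand-in  E = c1 * sqrt(count * mean_area) + noise
    (abstract streams only; rendered scenes get real Sobel energy),
  * detector imperfections: missed splashes, false positives, box jitter.

`gen_scene_images` additionally renders frames: a low-frequency ripple
field with glare blobs, splashes as 2-4 superimposed anisotropic bright
Gaussians with speckle (fragmented boundaries), and YOLO-format labels
for each splash's minimum bounding rectangle.  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .detection import Box, Detection
from .intensity import WindowFeatures


@dataclass(frozen=True)
class SessionSpec:
    duration: int = 300                 # windows (= seconds at 1 fps sampling)
    # stage profile fractions (calm, rise, plateau, decay; tail = remainder)
    calm_frac: float = 0.10
    rise_frac: float = 0.15
    plateau_frac: float = 0.30
    decay_frac: float = 0.35
    lambda_max: float = 8.0             # peak splashes per window
    area_mu: float = 5.7                # log-normal ln(px^2) location (~300 px^2)
    area_sigma: float = 0.5
    # splash magnitude grows with feeding activity (strong feeding produces
    # large splashes, weak feeding small sporadic ones): the log-area
    # location shifts by area_activity_gain * (a(t) - 0.5)
    area_activity_gain: float = 1.0
    frame_size: tuple = (1280, 1040)    # (width, height) of the virtual frame
    # detector noise model
    false_positive_rate: float = 0.2    # expected FPs per window
    miss_rate: float = 0.05
    jitter_sigma: float = 2.0           # box-corner jitter, px
    # texture-energy stand-in
    energy_coef: float = 1.0
    energy_noise: float = 2.0
    # rendering
    ripple_amplitude: float = 12.0
    glare_count: int = 3
    glare_intensity: float = 40.0
    splash_scale: float = 12.0          # splash Gaussian sigma, px (640-scale)
    stage_cuts: tuple = (0.05, 0.35, 0.7)
    seed: int = 0

    def __post_init__(self):
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.lambda_max < 0 or self.false_positive_rate < 0 or self.miss_rate < 0:
            raise ValueError("rates must be nonnegative")
        fr = self.calm_frac + self.rise_frac + self.plateau_frac + self.decay_frac
        if fr > 1.0 + 1e-9:
            raise ValueError("stage fractions exceed 1")


@dataclass
class GeneratedWindow:
    t: int
    activity: float          # a(t) in [0,1]
    rate: float              # lambda(t) = lambda_max * a(t)
    label: int               # ground-truth stage level, 0..3
    detections: list
    energy: float            # simulated texture energy


def activity_profile(spec: SessionSpec) -> np.ndarray:
    """Piecewise calm -> linear rise -> plateau -> linear decay -> tail."""
    n = spec.duration
    n_calm = int(n * spec.calm_frac)
    n_rise = int(n * spec.rise_frac)
    n_plat = int(n * spec.plateau_frac)
    n_decay = int(n * spec.decay_frac)
    a = np.zeros(n)
    i = n_calm
    if n_rise:
        a[i:i + n_rise] = np.linspace(0, 1, n_rise, endpoint=False)
    i += n_rise
    a[i:i + n_plat] = 1.0
    i += n_plat
    if n_decay:
        a[i:i + n_decay] = np.linspace(1, 0, n_decay, endpoint=False)
    return a


def label_stage(a_t, cuts=(0.05, 0.35, 0.7)) -> np.ndarray | int:
    """Half-open binning of activity into the four stage levels."""
    cuts = tuple(cuts)
    if not all(0 < c < 1 for c in cuts) or not all(
            b > a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cuts must be strictly increasing in (0,1)")
    a = np.asarray(a_t, dtype=np.float64)
    out = np.digitize(a, cuts)
    return int(out) if np.isscalar(a_t) else out


def _sample_box(rng, spec, area_scale=1.0, activity=0.5) -> Box:
    w_img, h_img = spec.frame_size
    mu = spec.area_mu + spec.area_activity_gain * (activity - 0.5)
    area = float(np.exp(rng.normal(mu, spec.area_sigma))) * area_scale
    ar = float(np.exp(rng.normal(0.0, 0.3)))
    bw = min(np.sqrt(area * ar), w_img - 2)
    bh = min(np.sqrt(area / ar), h_img - 2)
    cx = rng.uniform(bw / 2 + 1, w_img - bw / 2 - 1)
    cy = rng.uniform(bh / 2 + 1, h_img - bh / 2 - 1)
    return Box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2)


def _jitter_box(rng, b: Box, sigma: float, frame) -> Box:
    w_img, h_img = frame
    j = rng.normal(0, sigma, 4)
    x1 = float(np.clip(b.x_min + j[0], 0, w_img - 2))
    y1 = float(np.clip(b.y_min + j[1], 0, h_img - 2))
    x2 = float(np.clip(b.x_max + j[2], x1 + 1, w_img))
    y2 = float(np.clip(b.y_max + j[3], y1 + 1, h_img))
    return Box(x1, y1, x2, y2)


def gen_detection_stream(spec: SessionSpec) -> list:
    """Abstract per-window detection stream with ground-truth stage labels."""
    rng = np.random.default_rng(spec.seed)
    prof = activity_profile(spec)
    labels = label_stage(prof, spec.stage_cuts)
    windows = []
    for t, a in enumerate(prof):
        lam = spec.lambda_max * a
        n_true = rng.poisson(lam)
        dets = []
        for _ in range(n_true):
            b = _sample_box(rng, spec, activity=a)
            if rng.uniform() < spec.miss_rate:
                continue
            b = _jitter_box(rng, b, spec.jitter_sigma, spec.frame_size)
            dets.append(Detection(b, float(rng.uniform(0.5, 1.0)), 0))
        for _ in range(rng.poisson(spec.false_positive_rate)):
            b = _sample_box(rng, spec, area_scale=0.4)
            dets.append(Detection(b, float(rng.uniform(0.25, 0.6)), 0))
        mean_area = float(np.mean([d.box.area for d in dets])) if dets else 0.0
        energy = 0.0
        if dets:
            energy = max(0.0, spec.energy_coef * np.sqrt(len(dets) * mean_area)
                         + rng.normal(0, spec.energy_noise))
        windows.append(GeneratedWindow(t, float(a), float(lam),
                                       int(labels[t]), dets, float(energy)))
    return windows


def stream_to_window_features(windows: list) -> list:
    """GeneratedWindow list -> WindowFeatures list for the intensity pipeline."""
    out = []
    for w in windows:
        f = len(w.detections)
        a = float(np.mean([d.box.area for d in w.detections])) if f else 0.0
        out.append(WindowFeatures(w.t, f, a, w.energy if f else 0.0))
    return out


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def render_frame(rng: np.random.Generator, spec: SessionSpec, n_splashes: int,
                 image_size=(640, 640)):
    """One water-surface frame plus ground-truth splash boxes.

    Returns (uint8 HxWx3 image, list[Box]).
    """
    w, h = image_size
    base = 70.0 + 10.0 * rng.uniform()
    ripple = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=12)
    ripple *= spec.ripple_amplitude / max(ripple.std(), 1e-9)
    img = base + ripple
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.glare_count):
        gx, gy = rng.uniform(0, w), rng.uniform(0, h)
        gs = rng.uniform(20, 60)
        img += spec.glare_intensity * np.exp(
            -((xx - gx) ** 2 + (yy - gy) ** 2) / (2 * gs ** 2))
    boxes = []
    for _ in range(n_splashes):
        base_scale = min(spec.splash_scale, min(w, h) / 8.0)
        scale = float(np.exp(rng.normal(np.log(base_scale), 0.35)))
        scale = min(scale, min(w, h) / 7.0)
        mx_ = min(3 * scale, (w - 2) / 2 - 1)
        my_ = min(3 * scale, (h - 2) / 2 - 1)
        cx = rng.uniform(mx_, w - mx_)
        cy = rng.uniform(my_, h - my_)
        xs, ys = [], []
        blob = np.zeros_like(img)
        for _ in range(rng.integers(2, 5)):
            dx, dy = rng.normal(0, scale * 0.6, 2)
            sx = scale * rng.uniform(0.5, 1.2)
            sy = scale * rng.uniform(0.3, 0.8)
            mx, my = cx + dx, cy + dy
            blob += np.exp(-((xx - mx) ** 2 / (2 * sx ** 2)
                             + (yy - my) ** 2 / (2 * sy ** 2)))
            xs += [mx - 2.5 * sx, mx + 2.5 * sx]
            ys += [my - 2.5 * sy, my + 2.5 * sy]
        speckle = rng.uniform(0.6, 1.0, blob.shape)
        img += 140.0 * blob * speckle
        x1, y1 = max(min(xs), 0.0), max(min(ys), 0.0)
        x2, y2 = min(max(xs), float(w)), min(max(ys), float(h))
        boxes.append(Box(x1, y1, x2, y2))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return np.stack([img] * 3, axis=-1), boxes


def gen_scene_images(spec: SessionSpec, out_dir, n_frames: int | None = None,
                     image_size=(640, 640)) -> dict:
    """Render frames + YOLO labels under out_dir/{images,labels}/.

    Frame t draws Poisson(lambda_max * a(t)) splashes.  Returns a
    manifest dict (also written as manifest.yaml).
    """
    import imageio.v3 as iio
    import yaml

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    prof = activity_profile(spec)
    n_frames = n_frames or spec.duration
    w, h = image_size
    entries = []
    for t in range(n_frames):
        a = prof[t % len(prof)]
        n_spl = rng.poisson(spec.lambda_max * a)
        img, boxes = render_frame(rng, spec, n_spl, image_size)
        name = f"frame_{t:05d}"
        iio.imwrite(out_dir / "images" / f"{name}.png", img)
        lines = []
        for b in boxes:
            cx = (b.x_min + b.x_max) / 2 / w
            cy = (b.y_min + b.y_max) / 2 / h
            bw = (b.x_max - b.x_min) / w
            bh = (b.y_max - b.y_min) / h
            lines.append(f"0 {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
        (out_dir / "labels" / f"{name}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else ""))
        entries.append({"image": f"images/{name}.png",
                        "label": f"labels/{name}.txt",
                        "n_splashes": len(boxes)})
    manifest = {"class_names": ["splash"], "image_size": list(image_size),
                "seed": spec.seed, "frames": entries}
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest
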