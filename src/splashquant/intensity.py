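"""Feeding-intensity quantification from per-frame splash detections.

The session is partitioned into fixed-length time windows (default 1 s,
matching 1 fps frame sampling).  Per window the pipeline computes

    f_t : splash-event count (detections per window)
    A_t : mean detected-box pixel area (0 for empty windows)
    E_t : texture-disturbance energy — mean squared Sobel-gradient
          magnitude over the pixel union of the detected boxes

detrends and min-max normalizes each series, fuses them into the
composite score

    S_t = alpha * f~_t + beta * A~_t + gamma * E~_t,   alpha+beta+gamma = 1

maps S_t onto four discrete levels (none / weak / moderate / strong) via
thresholds T0 < T1 < T2 with a dwell-time constraint, and drives a
threshold-dwell feeding controller with hysteresis: pause when S_t < S*
for more than tau consecutive windows, resume within the observation
window only on a rebound above the recovery threshold S_re (or a local
peak above eta), otherwise stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .detection import Box, Detection

LEVEL_NAMES = ("none", "weak", "moderate", "strong")


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class DetectionFrame:
    timestamp: float
    detections: list
    gray: np.ndarray | None = None   # grayscale frame for texture energy


@dataclass
class WindowFeatures:
    t: int
    f: int
    area: float
    energy: float


@dataclass
class NormalizedFeatures:
    f: np.ndarray
    area: np.ndarray
    energy: np.ndarray


@dataclass(frozen=True)
class FusionWeights:
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        w = (self.alpha, self.beta, self.gamma)
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"weights {w} must be nonnegative and sum to 1")


@dataclass(frozen=True)
class LevelThresholds:
    t0: float
    t1: float
    t2: float
    dwell: int = 0

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("thresholds must satisfy T0 < T1 < T2")
        if self.dwell < 0:
            raise ValueError("dwell must be >= 0")


@dataclass(frozen=True)
class ControllerConfig:
    """Defaults are simulator-demo values, not field-calibrated ones."""
    s_star: float = 0.15
    tau_stop: int = 5
    s_recover: float = 0.25
    eta: float = 0.5

    def __post_init__(self):
        if self.s_recover < self.s_star:
            raise ValueError("hysteresis requires S_re >= S*")
        if self.eta < self.s_recover:
            raise ValueError("peak threshold eta must be >= S_re")
        if self.tau_stop < 1:
            raise ValueError("tau_stop must be >= 1")


@dataclass
class IntensitySeries:
    score: np.ndarray
    levels: list
    states: list
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# window features
# ---------------------------------------------------------------------------

def texture_energy(gray: np.ndarray, boxes: list) -> float:
    """Mean squared 3x3-Sobel gradient magnitude over the box-union mask.

    Overlapping boxes contribute once (union semantics).  An empty box
    list yields 0 by contract.
    """
    if not boxes:
        return 0.0
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    mask = np.zeros((h, w), dtype=bool)
    for b in boxes:
        if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
            raise ValueError(f"box {b} outside {w}x{h} frame")
        mask[int(np.floor(b.y_min)):int(np.ceil(b.y_max)),
             int(np.floor(b.x_min)):int(np.ceil(b.x_max))] = True
    if not mask.any():
        return 0.0
    gx = ndimage.sobel(gray, axis=1)
    gy = ndimage.sobel(gray, axis=0)
    return float(((gx ** 2 + gy ** 2)[mask]).mean())


def compute_window_features(frames: list, window_s: float = 1.0) -> list:
    """Aggregate per-frame detections into per-window (f, A, E) triples."""
    if not frames:
        raise ValueError("empty session")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    ts = [f.timestamp for f in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    t0 = ts[0]
    n_windows = int((ts[-1] - t0) / window_s) + 1
    buckets: list = [[] for _ in range(n_windows)]
    for f in frames:
        buckets[int((f.timestamp - t0) / window_s)].append(f)
    out = []
    for t, frames_in in enumerate(buckets):
        dets = [d for fr in frames_in for d in fr.detections]
        f_t = len(dets)
        if f_t == 0:
            out.append(WindowFeatures(t, 0, 0.0, 0.0))
            continue
        a_t = float(np.mean([d.box.area for d in dets]))
        energies = [
            texture_energy(fr.gray, [d.box for d in fr.detections])
            for fr in frames_in if fr.detections and fr.gray is not None
        ]
        e_t = float(np.mean(energies)) if energies else 0.0
        out.append(WindowFeatures(t, f_t, a_t, e_t))
    return out


# ---------------------------------------------------------------------------
# normalization and fusion
# ---------------------------------------------------------------------------

def detrend(series, method: str = "linear", window: int = 11) -> np.ndarray:
    """Remove a session-level baseline; default is the OLS linear fit."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < 2:
        raise ValueError("detrend needs at least 2 points")
    if method == "none":
        return x.copy()
    if method == "linear":
        t = np.arange(x.size)
        slope, intercept = np.polyfit(t, x, 1)
        return x - (slope * t + intercept)
    if method == "moving_median":
        return x - ndimage.median_filter(x, size=window, mode="nearest")
    raise ValueError(f"unknown detrend method {method!r}")


def minmax_normalize(series) -> np.ndarray:
    """(x - min) / (max - min); a constant series maps to all zeros."""
    x = np.asarray(series, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def normalize_features(features: list, detrend_method: str = "linear") -> NormalizedFeatures:
    f = np.array([w.f for w in features], dtype=np.float64)
    a = np.array([w.area for w in features], dtype=np.float64)
    e = np.array([w.energy for w in features], dtype=np.float64)
    return NormalizedFeatures(
        f=minmax_normalize(detrend(f, detrend_method)),
        area=minmax_normalize(detrend(a, detrend_method)),
        energy=minmax_normalize(detrend(e, detrend_method)),
    )


def fuse_score(nf: NormalizedFeatures, w: FusionWeights) -> np.ndarray:
    return w.alpha * nf.f + w.beta * nf.area + w.gamma * nf.energy


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _macro_f1(truth: np.ndarray, pred: np.ndarray, n_cls: int = 4) -> float:
    f1s = []
    for c in range(n_cls):
        tp = np.sum((pred == c) & (truth == c))
        fp = np.sum((pred == c) & (truth != c))
        fn = np.sum((pred != c) & (truth == c))
        if tp + fp + fn == 0:
            continue
        f1s.append(2 * tp / max(2 * tp + fp + fn, 1))
    return float(np.mean(f1s)) if f1s else 0.0


def cohen_kappa(truth, pred, n_cls: int = 4) -> float:
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    n = len(truth)
    po = np.mean(truth == pred)
    pe = sum(np.mean(truth == c) * np.mean(pred == c) for c in range(n_cls))
    if pe >= 1.0:
        return 0.0
    return float((po - pe) / (1.0 - pe))


def thresholds_from_labels(score: np.ndarray, labels: np.ndarray,
                           dwell: int = 0) -> LevelThresholds:
    """Label-conditional quantile thresholds: T_k is the score quantile at
    the cumulative proportion of labels below level k."""
    labels = np.asarray(labels, dtype=int)
    cuts = []
    for k in (1, 2, 3):
        p = np.mean(labels < k)
        cuts.append(float(np.quantile(score, min(max(p, 0.0), 1.0))))
    # enforce strict ordering for degenerate label mixes
    for i in (1, 2):
        if cuts[i] <= cuts[i - 1]:
            cuts[i] = cuts[i - 1] + 1e-9
    return LevelThresholds(*cuts, dwell=dwell)


def _threshold_candidates(score: np.ndarray, labels: np.ndarray) -> list:
    """Label-conditional quantile candidates for each of the three cuts."""
    cands = []
    for k in (1, 2, 3):
        cs = {float(np.quantile(score, np.mean(labels < k)))}
        lo, hi = score[labels == k - 1], score[labels == k]
        if lo.size and hi.size:
            for ql, qh in ((0.75, 0.25), (0.9, 0.1), (0.5, 0.5)):
                cs.add(float((np.quantile(lo, ql) + np.quantile(hi, qh)) / 2))
        cands.append(sorted(cs))
    return cands


def calibrate_weights(nf: NormalizedFeatures, labels, objective: str = "spearman",
                      grid_step: float = 0.05, dwell: int = 0):
    """Exhaustive search for (alpha, beta, gamma) and level thresholds.

    Scans the full simplex grid (step `grid_step`) and, for the
    classification objectives, the label-conditional quantile threshold
    candidates, maximizing the chosen agreement objective between the
    fused score and expert levels.  Ties break toward the
    lexicographically smallest weight triple.  Returns
    (FusionWeights, LevelThresholds).
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration needs at least 2 distinct labels")
    if objective not in ("spearman", "macro_f1", "kappa"):
        raise ValueError(f"unknown objective {objective!r}")
    score_fn = _macro_f1 if objective == "macro_f1" else cohen_kappa
    n = int(round(1.0 / grid_step))
    best_w, best_th, best_obj = None, None, -np.inf
    for i in range(n + 1):
        for j in range(n + 1 - i):
            w = FusionWeights(i / n, j / n, (n - i - j) / n)
            s = fuse_score(nf, w)
            if objective == "spearman":
                obj = (-np.inf if np.ptp(s) == 0
                       else stats.spearmanr(s, labels).statistic)
                th = None
            else:
                obj, th = -np.inf, None
                cands = _threshold_candidates(s, labels)
                for t0 in cands[0]:
                    for t1 in cands[1]:
                        if t1 <= t0:
                            continue
                        for t2 in cands[2]:
                            if t2 <= t1:
                                continue
                            o = score_fn(labels, np.digitize(s, [t0, t1, t2]))
                            if o > obj + 1e-12:
                                obj, th = o, (t0, t1, t2)
            if obj > best_obj + 1e-12:
                best_w, best_th, best_obj = w, th, obj
    s = fuse_score(nf, best_w)
    if best_th is None:
        return best_w, thresholds_from_labels(s, labels, dwell=dwell)
    return best_w, LevelThresholds(*best_th, dwell=dwell)


# ---------------------------------------------------------------------------
# level mapping and controller
# ---------------------------------------------------------------------------

def map_levels(score, th: LevelThresholds, as_indices: bool = False):
    """Half-open threshold bins with a dwell-time constraint.

    The emitted level changes to the instantaneous level only once that
    level has persisted for strictly more than `th.dwell` consecutive
    windows; dwell=0 reduces to the instantaneous binning.
    """
    s = np.asarray(score, dtype=np.float64)
    inst = np.digitize(s, [th.t0, th.t1, th.t2])
    out = np.empty_like(inst)
    emitted = inst[0]
    cand, run = emitted, 0
    for t, lv in enumerate(inst):
        if lv == emitted:
            cand, run = emitted, 0
        elif lv == cand:
            run += 1
            if run > th.dwell:
                emitted = lv
                cand, run = lv, 0
        else:
            cand, run = lv, 1
            if run > th.dwell:
                emitted = lv
                run = 0
        out[t] = emitted
    if as_indices:
        return out
    return [LEVEL_NAMES[i] for i in out]


FEEDING, PAUSED, RESUMED, STOPPED = "FEEDING", "PAUSED", "RESUMED", "STOPPED"


def feeding_controller(score, cc: ControllerConfig = ControllerConfig()):
    """Threshold-dwell stopping rule with hysteresis.

    FEEDING -> PAUSED after S_t < S* for more than tau_stop consecutive
    windows; during the tau_stop-window observation period after a pause
    a rebound above S_re (or a within-window peak above eta) resumes
    feeding, otherwise the controller stops for the rest of the session.
    Returns (state list, event list).
    """
    s = np.asarray(score, dtype=np.float64)
    states, events = [], []
    state = FEEDING
    below = 0
    observe_left = 0
    for t, v in enumerate(s):
        if state == FEEDING:
            below = below + 1 if v < cc.s_star else 0
            if below > cc.tau_stop:
                state = PAUSED
                observe_left = cc.tau_stop
                events.append({"window": t, "event": "pause"})
            states.append(state)
        elif state == PAUSED:
            if v > cc.s_recover or v > cc.eta:
                events.append({"window": t, "event": "resume"})
                states.append(RESUMED)
                state = FEEDING      # staged re-feeding from the next window
                below = 0
            else:
                observe_left -= 1
                if observe_left <= 0:
                    state = STOPPED
                    events.append({"window": t, "event": "stop"})
                states.append(state)
        else:  # STOPPED is absorbing until the next feeding cycle
            states.append(STOPPED)
    return states, events


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def quantify_session(frames: list, weights: FusionWeights,
                     thresholds: LevelThresholds,
                     controller: ControllerConfig | None = None,
                     window_s: float = 1.0, detrend_method: str = "linear"):
    """Frames -> per-window feature/score/level/state table (DataFrame)."""
    import pandas as pd

    feats = compute_window_features(frames, window_s)
    nf = normalize_features(feats, detrend_method)
    s = fuse_score(nf, weights)
    levels = map_levels(s, thresholds)
    states, events = feeding_controller(s, controller or ControllerConfig())
    df = pd.DataFrame({
        "t": [w.t for w in feats],
        "f": [w.f for w in feats],
        "A": [w.area for w in feats],
        "E": [w.energy for w in feats],
        "f_norm": nf.f, "A_norm": nf.area, "E_norm": nf.energy,
        "S": s, "level": levels, "controller_state": states,
    })
    return df, events
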