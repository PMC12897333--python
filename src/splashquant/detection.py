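"""Boxes, NMS, raw-prediction decoding and detection metrics.

Boxes use 0-based float pixel coordinates with the half-open convention
[x_min, x_max) x [y_min, y_max).  Evaluation follows the COCO-style
metric family: greedy score-descending one-to-one matching per image at
each IoU threshold, average precision from the 101-point interpolated
precision-recall curve, and mAP@0.5:0.95 as the mean of AP over the
thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .nn.autograd import Tensor

IOU_THRESHOLDS_COCO = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Box:
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


@dataclass(frozen=True)
class Detection:
    box: Box
    score: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(detections: list, iou_threshold: float) -> list:
    """Greedy score-descending non-maximum suppression, per class."""
    order = sorted(range(len(detections)),
                   key=lambda i: -detections[i].score)
    keep: list = []
    for i in order:
        d = detections[i]
        if all(k.class_id != d.class_id or iou(k.box, d.box) <= iou_threshold
               for k in keep):
            keep.append(d)
    return keep


def decode_predictions(raw: dict, strides: dict, num_classes: int,
                       reg_max: int = 16) -> list:
    """Raw per-scale maps -> per-image arrays (n, 6): x1,y1,x2,y2,score,cls.

    Box distances come from the DFL expectation (softmax over reg_max
    bins times the bin index), scaled by the stride; scores are the
    sigmoid class activations.
    """
    some = next(iter(raw.values()))
    B = (some.data if isinstance(some, Tensor) else some).shape[0]
    per_image = [[] for _ in range(B)]
    proj = np.arange(reg_max, dtype=np.float32)
    for scale, t in raw.items():
        a = t.data if isinstance(t, Tensor) else np.asarray(t)
        s = strides[scale]
        b, ch, h, w = a.shape
        a = a.reshape(b, ch, h * w)
        dist = a[:, :4 * reg_max].reshape(b, 4, reg_max, h * w)
        dist = np.exp(dist - dist.max(axis=2, keepdims=True))
        dist /= dist.sum(axis=2, keepdims=True)
        ltrb = np.einsum("bdrn,r->bdn", dist, proj) * s
        gy, gx = np.divmod(np.arange(h * w), w)
        ax, ay = (gx + 0.5) * s, (gy + 0.5) * s
        boxes = np.stack([ax - ltrb[:, 0], ay - ltrb[:, 1],
                          ax + ltrb[:, 2], ay + ltrb[:, 3]], axis=1)
        scores = expit(a[:, 4 * reg_max:4 * reg_max + num_classes])
        cls = scores.argmax(axis=1)
        conf = scores.max(axis=1)
        for i in range(b):
            per_image[i].append(np.column_stack(
                [boxes[i].T, conf[i], cls[i]]))
    return [np.concatenate(p, axis=0) for p in per_image]


def postprocess(raw: dict, strides: dict, num_classes: int = 1,
                conf_threshold: float = 0.25, nms_iou: float = 0.45,
                reg_max: int = 16) -> list:
    """Decode + confidence filter + NMS; list of Detection lists per image."""
    if not (0.0 <= conf_threshold <= 1.0 and 0.0 <= nms_iou <= 1.0):
        raise ValueError("conf_threshold and nms_iou must be in [0,1]")
    out = []
    for arr in decode_predictions(raw, strides, num_classes, reg_max):
        dets = []
        for x1, y1, x2, y2, sc, c in arr:
            if sc < conf_threshold or x2 <= x1 or y2 <= y1:
                continue
            dets.append(Detection(Box(x1, y1, x2, y2), float(sc), int(c)))
        out.append(nms(dets, nms_iou))
    return out


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    map50: float
    map5095: float
    ap_per_threshold: dict = field(default_factory=dict)


def _match_image(preds: list, gts: list, thr: float) -> list:
    """Greedy one-to-one matching; returns per-pred is-TP flags.

    Predictions are processed in descending score; each is matched to
    the unused same-class ground truth with the highest IoU >= thr (ties
    on IoU broken toward the lower ground-truth index).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    used = [False] * len(gts)
    flags = [False] * len(preds)
    for i in order:
        p = preds[i]
        best, best_iou = -1, thr
        for j, (gc, gb) in enumerate(gts):
            if used[j] or gc != p.class_id:
                continue
            v = iou(p.box, gb)
            if v > best_iou or (v == best_iou and best == -1 and v >= thr and v > 0):
                best, best_iou = j, v
        if best >= 0:
            used[best] = True
            flags[i] = True
    return flags


def _average_precision(scores: np.ndarray, flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP from scored TP/FP flags."""
    if n_gt == 0:
        return float("nan")
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, sampled at 101 recall points
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


def evaluate(predictions: dict, ground_truth: dict,
             iou_thresholds=IOU_THRESHOLDS_COCO) -> EvalResult:
    """COCO-style evaluation.

    predictions: image_id -> list[Detection]
    ground_truth: image_id -> list of (class_id, Box)
    Every predicted image id must exist in the ground-truth set (images
    with no predictions need not appear in `predictions`).
    """
    missing = set(predictions) - set(ground_truth)
    if missing:
        raise KeyError(f"predictions reference unknown image ids: {sorted(missing)}")
    image_ids = sorted(ground_truth)
    classes = sorted(
        {c for gts in ground_truth.values() for c, _ in gts}
        | {d.class_id for ds in predictions.values() for d in ds}
    )

    ap_per_thr: dict = {}
    tp50 = fp50 = 0
    n_gt_total = sum(len(v) for v in ground_truth.values())
    for thr in iou_thresholds:
        aps = []
        for cls in classes:
            scores, flags = [], []
            n_gt = 0
            for img in image_ids:
                gts = [g for g in ground_truth[img] if g[0] == cls]
                preds = [p for p in predictions.get(img, []) if p.class_id == cls]
                n_gt += len(gts)
                f = _match_image(preds, gts, thr)
                scores.extend(p.score for p in preds)
                flags.extend(f)
                if np.isclose(thr, 0.5):
                    tp50 += sum(f)
                    fp50 += len(f) - sum(f)
            ap = _average_precision(np.asarray(scores), np.asarray(flags, bool), n_gt)
            if not np.isnan(ap):
                aps.append(ap)
        ap_per_thr[float(thr)] = float(np.mean(aps)) if aps else 0.0

    fn50 = n_gt_total - tp50
    precision = tp50 / (tp50 + fp50) if tp50 + fp50 else 0.0
    recall = tp50 / (tp50 + fn50) if tp50 + fn50 else 0.0
    map50 = ap_per_thr.get(0.5, 0.0)
    map5095 = float(np.mean(list(ap_per_thr.values())))
    return EvalResult(tp=int(tp50), fp=int(fp50), fn=int(fn50),
                      precision=float(precision), recall=float(recall),
                      map50=map50, map5095=map5095,
                      ap_per_threshold=ap_per_thr)
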