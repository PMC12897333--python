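"""Composite detection loss: classification + box distance + DFL.

Anchor-free formulation over the per-scale prediction maps.  Each ground
truth box is assigned to the grid cell containing its centre at the
scale whose stride best matches the box size (a deterministic
centre-cell assigner).  At positive anchors the box branch is trained
with an L1 penalty on the DFL-expected left/top/right/bottom distances
(in stride units) plus the distribution-focal cross-entropy on the two
neighbouring bins; the class branch is trained with sigmoid
cross-entropy over all anchors.
"""

from __future__ import annotations

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor


def assign_targets(labels: list, scales: list, strides: list, grids: list,
                   reg_max: int) -> dict:
    """Map ground-truth boxes to (image, flat-anchor) positives.

    labels: per image an (n,5) array [class, x1, y1, x2, y2] in pixels.
    Returns flat indices into the concatenation of all scale grids plus
    per-positive class ids and ltrb distance targets in stride units.
    """
    offsets = np.cumsum([0] + [h * w for h, w in grids])
    bi, ni, cls_ids, ltrb = [], [], [], []
    for img, lab in enumerate(labels):
        for row in np.atleast_2d(np.asarray(lab, dtype=np.float64)):
            if row.size == 0:
                continue
            c, x1, y1, x2, y2 = row
            side = max(x2 - x1, y2 - y1)
            k = int(np.argmin([abs(np.log2(max(side, 1e-3) / (4.0 * s)))
                               for s in strides]))
            s = strides[k]
            h, w = grids[k]
            cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
            gx = min(int(cx / s), w - 1)
            gy = min(int(cy / s), h - 1)
            ax, ay = (gx + 0.5) * s, (gy + 0.5) * s
            d = np.array([ax - x1, ay - y1, x2 - ax, y2 - ay]) / s
            d = np.clip(d, 0.0, reg_max - 1 - 1e-3)
            bi.append(img)
            ni.append(offsets[k] + gy * w + gx)
            cls_ids.append(int(c))
            ltrb.append(d)
    return {
        "img": np.asarray(bi, dtype=np.int64),
        "anchor": np.asarray(ni, dtype=np.int64),
        "cls": np.asarray(cls_ids, dtype=np.int64),
        "ltrb": np.asarray(ltrb, dtype=np.float32).reshape(-1, 4),
    }


def detection_loss(outs: dict, labels: list, strides: dict, nc: int,
                   reg_max: int, weights=(0.5, 1.0, 0.5)) -> tuple[Tensor, dict]:
    """Total loss over a batch; returns (scalar Tensor, component floats)."""
    scales = list(outs.keys())
    stride_list = [strides[s] for s in scales]
    grids = [(outs[s].shape[2], outs[s].shape[3]) for s in scales]
    B = outs[scales[0]].shape[0]

    flat = []
    for s in scales:
        t = outs[s]
        b, ch, h, w = t.shape
        flat.append(t.reshape(b, ch, h * w).transpose(0, 2, 1))
    pred = ag.concat(flat, axis=1)                    # (B, Ntot, 4*reg_max+nc)
    n_total = pred.shape[1]

    tgt = assign_targets(labels, scales, stride_list, grids, reg_max)
    npos = len(tgt["img"])

    cls_logits = ag.split(pred, [4 * reg_max, nc], axis=2)[1]
    cls_t = np.zeros((B, n_total, nc), dtype=np.float32)
    if npos:
        cls_t[tgt["img"], tgt["anchor"], tgt["cls"]] = 1.0
    denom = max(npos, 1)
    l_cls = ag.bce_with_logits(cls_logits, cls_t) * (1.0 / denom)

    if npos == 0:
        w_cls = weights[0]
        total = l_cls * w_cls
        return total, {"cls": l_cls.item(), "box": 0.0, "dfl": 0.0,
                       "total": total.item(), "num_pos": 0}

    box_logits = ag.split(pred, [4 * reg_max, nc], axis=2)[0]
    pos = box_logits[(tgt["img"], tgt["anchor"])]     # (P, 4*reg_max)
    dist = pos.reshape(npos, 4, reg_max).softmax(axis=-1)
    proj = Tensor(np.arange(reg_max, dtype=np.float32).reshape(reg_max, 1))
    expect = (dist @ proj).reshape(npos, 4)

    diff = expect - Tensor(tgt["ltrb"])
    l_box = (diff * diff).mean()                      # smooth surrogate (L2)

    t = tgt["ltrb"]
    lo = np.floor(t).astype(np.int64)
    hi = np.minimum(lo + 1, reg_max - 1)
    w_hi = (t - lo).astype(np.float32)
    w_lo = 1.0 - w_hi
    logp = (dist + 1e-9).log()
    ii = np.repeat(np.arange(npos), 4)
    jj = np.tile(np.arange(4), npos)
    p_lo = logp[(ii, jj, lo.ravel())]
    p_hi = logp[(ii, jj, hi.ravel())]
    l_dfl = -(p_lo * Tensor(w_lo.ravel()) + p_hi * Tensor(w_hi.ravel())).mean()

    w_cls, w_box, w_dfl = weights
    total = l_cls * w_cls + l_box * w_box + l_dfl * w_dfl
    comps = {"cls": l_cls.item(), "box": l_box.item(), "dfl": l_dfl.item(),
             "total": total.item(), "num_pos": npos}
    return total, comps
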