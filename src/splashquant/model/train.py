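"""Training loop and checkpointing for the splash detector."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..nn.modules import SGD
from .detector import ModelConfig, SplashDetector, build_model
from .loss import detection_loss


def _prep_image(img: np.ndarray) -> np.ndarray:
    """HWC uint8/float image -> (3,H,W) float32 in [0,1]."""
    a = np.asarray(img)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    a = a.astype(np.float32)
    if a.max() > 1.5:
        a = a / 255.0
    return a.transpose(2, 0, 1)


def fit(net: SplashDetector, images: list, labels: list, epochs: int = 5,
        batch_size: int = 4, lr: float = 0.01, momentum: float = 0.9,
        seed: int = 0, verbose: bool = False) -> dict:
    """Train on (image, label) pairs; labels are (n,5) [cls,x1,y1,x2,y2] px.

    Returns a history dict with per-epoch mean losses.  Raises on an
    empty dataset and aborts with a diagnostic if the loss goes NaN.
    """
    if len(images) == 0:
        raise ValueError("empty training dataset")
    if len(images) != len(labels):
        raise ValueError("images/labels length mismatch")
    rng = np.random.default_rng(seed)
    opt = SGD(net.parameters(), lr=lr, momentum=momentum)
    net.train()
    xs = [_prep_image(im) for im in images]
    n = len(xs)
    history = {"epoch_loss": [], "components": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, comps_acc = [], []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            batch = np.stack([xs[i] for i in idx])
            lab = [labels[i] for i in idx]
            outs = net.forward(batch)
            loss, comps = detection_loss(outs, lab, net.strides,
                                         net.cfg.num_classes, net.cfg.reg_max)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {comps}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            comps_acc.append(comps)
        mean = float(np.mean(losses))
        history["epoch_loss"].append(mean)
        history["components"].append(
            {k: float(np.mean([c[k] for c in comps_acc]))
             for k in ("cls", "box", "dfl", "total")}
        )
        if verbose:
            print(f"epoch {epoch}: loss {mean:.4f}")
    return history


def save_checkpoint(net: SplashDetector, path) -> None:
    state = net.state_dict()
    np.savez_compressed(
        path,
        __config__=np.frombuffer(
            json.dumps(net.cfg.to_dict()).encode(), dtype=np.uint8
        ),
        **state,
    )


def load_checkpoint(path) -> SplashDetector:
    with np.load(path) as z:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(z["__config__"]).decode())
        )
        net = build_model(cfg)
        net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return net
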