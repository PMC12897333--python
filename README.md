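# splashquant

Vision-based feeding management for aquaculture: when a school of fish
(the motivating system is net-cage culture of large yellow croaker)
competes for feed pellets, it disturbs the water surface with transient
splashes.  The frequency, size and texture of those splashes track how
hungry the school is, so a camera above the cage plus a small-object
detector can replace feeding "by experience" with a measured,
closed-loop signal.  `splashquant` implements that pipeline end to end
for researchers and aquaculture engineers:

1. **Splash detector** — a YOLO11s-style one-stage network with three
   targeted modifications for small, fragmented, low-contrast splashes:
   * **EGMA** (edge-guided multi-dimensional attention) units on the
     backbone C3k2 stages 2/4/6/8.  EGMA predicts an edge-saliency map
     `E = σ(BN(Conv3×3(X)))`, pools edge-weighted channel statistics
     `G = GAP(X ⊙ E)`, derives channel weights `Ac = σ(MLP(G))` and
     recalibrates the features as `Y = X ⊙ Ac ⊙ (1 + E)`.
   * **ADown**, a three-branch stride-2 downsampler (average-pool →
     1×1 conv, stride-2 3×3 conv, max-pool → 1×1 conv) whose output
     channels split by `Ca = Cb = ⌊C2/3⌋, Cc = C2 − Ca − Cb`,
     replacing the stride-2 convolutions of the PAN aggregation path.
   * an optional **P2 head** (stride 4) extending the usual P3–P5
     outputs to four scales for extremely small splashes.

   The network, its training loop and its autograd engine are pure
   numpy — no deep-learning framework is required.

2. **Feeding-intensity quantification** — per time window *t* (1 s
   default): splash count `f_t`, mean box area `A_t`, and Sobel
   texture energy `E_t` over the union of detected boxes; after
   detrending and min–max normalization these fuse into
   `S_t = α·f̃_t + β·Ã_t + γ·Ẽ_t` (α+β+γ = 1), which maps to the four
   field levels **none / weak / moderate / strong** through thresholds
   `T0 < T1 < T2` with a dwell-time constraint, and drives a
   threshold–dwell feeding controller with hysteresis (pause when
   `S_t < S*` for more than τ windows; resume only on a rebound above
   `S_re`, else stop).

3. **GBDT grading** — a gradient-boosted tree classifier over
   `(F_t, A_t, E_t)` producing four-level probabilities and a
   continuous intensity curve via the probability-expectation mapping
   `I_t = Σ_k p_k·v_k` with `v = (0, 1/3, 2/3, 1)`.

4. **Synthetic feeding scenes** — a seeded generator of detection
   streams and rendered water-surface frames (ripples, glare,
   multi-Gaussian splash blobs with YOLO labels) following the
   characteristic rise → plateau → decay activity profile, so the whole
   pipeline is testable without access to farm footage.

## Worked example

```python
from splashquant.model import ModelConfig, build_model, count_parameters

net = build_model(ModelConfig(egma_layers=(2, 4, 6, 8), use_adown=True))
print("total parameters (deploy form):", f"{count_parameters(net).total:,}")
```

```
total parameters (deploy form): 9,190,475
```

That is the full detector (EGMA + ADown, single `splash` class) counted
in deployment form, i.e. with batch-norm folded into the skeleton's
convolutions.  The baseline without either module is 9,413,187, so the
combination *removes* ~220 k parameters while adding attention.

Quantifying a synthetic 300-window feeding session:

```python
import numpy as np
from collections import Counter
from splashquant.synthetic import (SessionSpec, gen_detection_stream,
                                   stream_to_window_features)
from splashquant.intensity import (FusionWeights, LevelThresholds,
                                   ControllerConfig, normalize_features,
                                   fuse_score, map_levels, feeding_controller)

spec = SessionSpec(duration=300, lambda_max=8.0, seed=42)
windows = gen_detection_stream(spec)
nf = normalize_features(stream_to_window_features(windows),
                        detrend_method="none")
score = fuse_score(nf, FusionWeights(0.4, 0.3, 0.3))
levels = map_levels(score, LevelThresholds(0.2, 0.4, 0.6, dwell=1))
print("peak score:", round(float(score.max()), 3),
      "at window", int(score.argmax()))
print("level counts:", dict(Counter(levels)))
onset = int(np.argmax(score > 0.2))
states, events = feeding_controller(score[onset:],
                                    ControllerConfig(0.15, 5, 0.25, 0.5))
print(f"controller events (onset at t={onset}):",
      [(e["window"] + onset, e["event"]) for e in events])
```

```
peak score: 0.805 at window 110
level counts: {'none': 119, 'weak': 77, 'moderate': 98, 'strong': 6}
controller events (onset at t=40): [(256, 'pause'), (261, 'stop')]
```

The fused score peaks mid-session (the plateau), the dwell-constrained
level series steps through all four grades, and the controller pauses
feeding once the decay phase keeps `S_t` below `S* = 0.15` for more
than five consecutive windows — then stops after the five-window
observation period shows no rebound above `S_re = 0.25`.

A command-line interface wraps the same functionality:

```bash
splashquant --seed 1 simulate stream --duration 300 --out session.jsonl
splashquant quantify --detections session.jsonl --out series.csv
splashquant build-model --egma --adown        # prints the parameter report
```

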