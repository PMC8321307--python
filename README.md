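# fallwatch

Single-camera fall detection for assistive home monitoring. Falls among
people living alone are a leading cause of long lies and injury; a fixed RGB
camera plus silhouette analysis can raise an alarm without wearable sensors.
`fallwatch` implements the full pipeline: shadow-aware human-silhouette
extraction, a bounding-box angular projection-histogram posture descriptor,
a four-class posture classifier (bend / lie / sit / stand), and a four-rule
fall decision engine, together with seeded synthetic fixtures (posture
silhouettes, activity sequences, shadowed scenes) that exercise every stage
with known ground truth.

## Method

**Silhouette extraction.** A median-reference background model (first 50
frames) yields raw foreground; shadows are removed in two stages. A pixel is
a shadow *candidate* when it darkens the background without changing
chromaticity:

    α ≤ F_V/R_V ≤ β,  |F_S − R_S| ≤ τ_S,  circ|F_H − R_H| ≤ τ_H

with α = 0.21, β = 0.99, τ_H = 93, τ_S = 76. Candidate blobs are then kept
as shadow only if the background texture shows through: per blob, pixels
with Sobel magnitude ≥ τ_m = 6 in both frames vote on gradient-direction
agreement, Δθ_p = arccos(⟨∇F, ∇R⟩/|∇F||∇R|), and the blob is shadow iff

    C_B = (1/N) Σ_p 𝟙(τ_a − Δθ_p > 0) ≥ τ_c        (τ_a = π/10, τ_c = 0.2).

Blobs under 50 px are dropped; the rest cluster by rectangle distance
(threshold 50 px) and the cluster scoring `motion/(1 + d_prev)` becomes the
person.

**Posture descriptor.** The silhouette's bounding box is viewed from a point
`Ph = (x_c, 0)` above it and a point `Pv = (W−1, y_c)` beside it. Each view
fans the box into N = 10 equal angular sectors; counting pixels per sector
pair gives an N×N histogram ψ with Σψ(i,l) = M, normalized to ψ̂ = ψ/M. The
feature vector appends the two fan extents and their ratio:

    F_S = [ψ̂(i,l), θ_V, θ_H, θ_H/θ_V]   ∈ ℝ^(N²+3) = ℝ¹⁰³.

**Classifier.** C-SVM with RBF kernel (γ = 0.01, C = 100, one-vs-one),
evaluated by confusion matrix, accuracy, precision, recall and F-score under
stratified 10-fold cross-validation.

**Fall rules.** An alarm requires, jointly: (1) posture lie or bend; (2)
≥ 85% of the silhouette inside the floor mask; (3) ≤ 25 frames (~1 s at
25 fps) since the last stand/sit frame — deliberate lying takes > 80; and
(4) ≥ 25 consecutive settled frames afterwards (frame-to-frame silhouette
change ≤ 0.05 *and* drift from the posture's anchor silhouette ≤ 0.10).
One alarm per episode; re-arming requires a return to stand/sit.

## Worked example

```python
import numpy as np
from fallwatch import (feature_vector, kfold_cv, train_posture_model,
                       run_pipeline)
from fallwatch.synthetic import (posture_dataset, generate_sequence,
                                 ScenarioScript)

# 100 jittered silhouettes per posture class, descriptor features, 10-fold CV
masks, labels = posture_dataset(100, seed=7)
X = np.stack([feature_vector(m) for m in masks])
report = kfold_cv(X, labels, k=10, seed=7)
print(f"10-fold CV accuracy: {report.accuracy:.4f}")
print(report.confusion)

# a fast fall vs. a slow, deliberate lie-down through the full pipeline
model = train_posture_model(X, labels)
fall = generate_sequence(ScenarioScript(scenario="fall", transition_frames=18, seed=3))
print(run_pipeline(fall.masks, fall.floor, model).events)
lie = generate_sequence(ScenarioScript(scenario="lie_down", transition_frames=90, seed=3))
print(run_pipeline(lie.masks, lie.floor, model).events)
```

Output:

```
10-fold CV accuracy: 0.9900
[[100   0   0   0]
 [  0 100   0   0]
 [  0   0  96   4]
 [  0   0   0 100]]
[{'frame': 62, 'transition_frames': 15, 'coverage': 1.0,
  'rules': {'abnormal': True, 'floor': True, 'transition': True, 'inactive': True}}]
[]
```

Held-out posture accuracy is 99% (4 of 100 sitting silhouettes confused
with standing). The fall sequence raises exactly one alarm at frame 62: the
stand→lie transition took 15 frames (a fall-speed collapse), the body lies
fully inside the floor region, and it then stayed motionless for the
25-frame confirmation window. The same trajectory stretched over 90 frames —
a person lying down deliberately — raises none.

The same stages are scriptable from the shell:

```sh
fallwatch simulate --scenario fall --n 5 --seed 7 --out sims/
fallwatch featurize --masks sims/fall_0007/frames --out feats.csv
fallwatch detect --masks sims/fall_0007/frames --floor sims/fall_0007/floor.png \
                 --model model.bin --out report.json --trace trace.csv
```

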