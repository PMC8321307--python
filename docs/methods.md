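# Methods

`fallwatch` detects falls of a single person from one fixed RGB camera, in
four stages: silhouette extraction, posture description, posture
classification, and rule-based fall confirmation. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Silhouette extraction

**Background model.** The empty scene is modeled by the per-pixel,
per-channel median of the first `n_train = 50` frames, with a per-pixel
Euclidean-RGB tolerance `10 + 4·σ`, where σ is the worst per-channel
training standard deviation at that pixel and 10 gray levels is a floor
absorbing sensor noise. A pixel is raw foreground when its color distance to
the reference exceeds its tolerance. This is a deliberately simple stand-in
for heavier per-pixel background models: the interesting logic of this stage
is shadow handling, and the median reference doubles as the reference frame
the shadow tests need.

**Shadow removal** runs in two stages on HSV frames whose value channel has
been min–max normalized per image (a constant channel maps to zero — the
declared degenerate rule).

1. *Chromaticity pixel test.* Pixel p is a shadow candidate when
   `α ≤ F_V(p)/R_V(p) ≤ β`, `|F_S − R_S| ≤ τ_S`, and the circular hue
   difference (period 256) is `≤ τ_H`. Defaults: α = 0.21, β = 0.99,
   τ_H = 93, τ_S = 76. A zero reference value cannot form a ratio and is
   never shadow. Raising τ_S or τ_H can only enlarge the candidate set
   (monotonicity, tested).
2. *Gradient-direction correlation per blob.* Candidates are grouped into
   8-connected blobs. In each blob, pixels whose 3×3 Sobel magnitude (on the
   value channel expressed on the 0–255 scale) reaches τ_m = 6 in **both**
   frames compare gradient directions through the normalized dot product
   (argument clamped to [−1, 1]); the blob remains shadow iff the fraction
   of pixels with angle difference below τ_a = π/10 is at least τ_c = 0.2.
   Shadow preserves the background texture, so directions agree; an object
   overwrites it, so they do not. A blob with *no* textured pixel stays
   shadow: the chromaticity test flagged it and there is no gradient
   evidence to overturn that — the refinement stage exists to rescue
   textured foreground, not to rescue flat regions.

**Person selection.** Surviving foreground blobs below 50 px are dropped;
the rest are single-linkage clustered with a rectangle-gap threshold of
50 px (minimum Euclidean distance between bounding rectangles, closed form
for axis-aligned boxes, checked against exhaustive boundary search). Each
cluster scores `motion / (1 + d_prev)` — motion being the fraction of the
cluster's pixels absent from the previous frame's foreground (1 when there
is no history) and `d_prev` the centroid distance to the person's previous
box center (0 without history). The top-scoring cluster is the person; ties
break toward the nearer, then larger, cluster. The score operationalizes
"moving object near where the person last was" without committing to a
specific optical-flow algorithm.

## Posture descriptor

The silhouette's tight bounding box is observed from two exterior points:
`Ph = (x_c, 0)` on the box's center column at the top image row, and
`Pv = (W−1, y_c)` on the box's center row at the right image border (each
pushed one pixel outside the box if the box touches that border — strictly
exterior, or the viewing distance degenerates to zero). From each point the
fan of angles subtended by the box — computed as max − min of the four
corner angles in a signed-deviation measure — is split into N equal sectors
(N = 10 by default). Every silhouette pixel, taken at its center
(x + 0.5, y + 0.5), gets a horizontal sector i (from Ph) and a vertical
sector l (from Pv) by `floor((angle − fan_min)/Δ)` clamped to [0, N−1]
(boundary ties go up). The N×N count matrix ψ satisfies Σψ = M exactly;
ψ̂ = ψ/M sums to one. The classifier input appends the two fan extents and
their ratio: `F_S = [ψ̂ row-major, θ_V, θ_H, θ_H/θ_V]`, length N² + 3 = 103.

Numerical notes:

* The corner-extent fan coincides with the closed form
  `2·arctan(side/(2D))` for square boxes and guarantees every box pixel a
  valid sector for any aspect ratio. With this geometry the extent seen from
  the *top* grows with the box *width*, so θ_H/θ_V is larger for flat
  (lying) shapes than for upright ones — a consistent, discriminative
  ordering.
* The histogram depends only on pixel positions relative to the reference
  points, so rigid translation of mask, box and reference points together
  leaves ψ bit-identical (tested exactly).
* ψ̂ is approximately scale-invariant: at 2× resolution the fan geometry
  scales exactly and only rasterization moves mass between neighboring
  cells. Because binning is hard (integer counts, required for exactness
  against the per-pixel oracle), the residual L1 distance is aliasing-
  dominated: it stays below 0.05 when each bin spans ≳5 px of the box's
  narrow side (canonical postures at 140-px body scale measure ≤ 0.042) but
  grows for small silhouettes (≈0.27 for a 10-px-tall lying shape, where a
  bin is a single pixel row). Shapes much smaller than ~2N px per axis are
  outside the descriptor's design regime.
* Mirroring a shape about its box's vertical centerline exactly reverses
  the i-marginal; the l indices legitimately change, because mirrored
  pixels sit at different depths from Pv.

## Posture classifier

A C-SVM with RBF kernel (libsvm through scikit-learn's `SVC`), cost 100 and
γ = 0.01, one-vs-one multiclass over the label space 1 = bend, 2 = lie,
3 = sit, 4 = stand. No feature standardization: the histogram block lies in
[0, 1] and the angle features are bounded by π, so the tuned (C, γ) act on a
naturally bounded space. Evaluation reports a 4×4 confusion matrix,
micro-averaged accuracy (trace/total), and per-class one-vs-rest accuracy,
precision TP/(TP+FP), recall TP/(TP+FN) and F = 2PR/(P+R). These are the
conventional denominator placements; some write-ups of this method print
precision and recall with the denominators swapped, which this package does
not follow. Zero-denominator metrics report 0 with an explanatory flag.
Cross-validation uses stratified folds with a fixed seed, pooling held-out
predictions into one confusion matrix, and falls back to unstratified folds
with a warning when a class is smaller than the fold count.

## Fall rules

Per frame, four conditions:

1. **Abnormal posture** — classified lie or bend.
2. **Floor coverage** — ≥ 85% of the silhouette's pixels (not its box) lie
   inside the manually drawn floor mask from the scene's first frame.
3. **Fast transition** — ≤ 25 frames (1 s at 25 fps) since the last frame
   classified stand or sit. Deliberate lying takes > 80 frames. If no
   stand/sit frame was ever seen, the rule fails permanently (a person who
   enters the scene already down never alarms — conservative).
4. **Inactivity** — the settled posture persists for ≥ 25 consecutive
   frames.

The engine runs these as a window automaton. When rules 1–3 hold and the
frame is still, an *inactivity window* opens, latching the transition count
and storing the current silhouette as its *anchor*. The window keeps
counting while the posture stays abnormal, on the floor, and still;
stillness requires both the consecutive-frame silhouette change
(1 − IoU ≤ `motion_epsilon` = 0.05) **and**, when masks are available, the
drift from the anchor (1 − IoU ≤ `settle_epsilon` = 0.10). The anchor test
is essential: a person lowering themselves slowly moves less than any
flicker-tolerant epsilon between consecutive frames, yet drifts far from the
anchor within a few frames — drift resets the window, flicker does not.
Without it, slow lying with a transition just after a bend onset raises a
false alarm; with it, the window can only complete once the body is truly
settled, by which time a slow transition has exceeded 25 frames. When the
count reaches 25 the alarm fires once; the episode re-arms only after the
person is again seen standing or sitting (Algorithm-style loops would
otherwise re-fire every frame). After firing, the inactivity requirement is
reported as consumed, so the per-frame invariant "fall iff all four rule
flags" holds exactly.

Lowering the coverage threshold or raising the transition budget can only
keep or add alarms on a fixed stream (monotonicity, tested).

## Synthetic fixtures

All test inputs are generated from seeds; every generator is a pure function
of its seed.

* **Posture silhouettes** come from an articulated capsule body (shank,
  thigh, torso, head; proportions fixed at 0.25/0.22/0.56/0.10 of the body
  scale) with class-conditional joint angles: stand upright; lie with all
  segments horizontal; sit with the thigh folded forward; bend with the
  torso tipped 48–80°. Realistic variability: ±20% scale, ±15% segment
  width, 0.1 rad joint jitter, and 2-px boundary-flip noise followed by
  largest-component/fill cleanup (guaranteeing one 8-connected component).
  Default body scale 48 px in a 128×128 frame — a mid-distance person for a
  room camera.
* **Activity sequences** (120×160, floor = lower 60% of the frame) animate
  the same body: walking, then for falls a torso-first collapse reaching
  the floor within ≤ 25 frames, for deliberate lying the same trajectory
  stretched over ≥ 80 frames, plus sit, walk-only, and an elevated bend
  that straddles the floor boundary to exercise the coverage rule. The legs
  follow the torso once it passes 45°, so mid-transition frames look like a
  bend — never like a sit, which would reset the transition clock.
  Per-frame boundary noise (1-px ring, 6% flip rate during motion, 2.5% in
  sequences) keeps settled tails at ~2–4% frame-to-frame change, below the
  0.05 motion epsilon, as a stable segmentation of a still person would be.
* **Shadow scenes** build a sinusoidally textured background (value range
  ~[95, 225], so Sobel magnitudes comfortably exceed τ_m), dim an
  elliptical region's value channel by ρ ∈ [0.5, 0.9] with hue and
  saturation preserved (a chromaticity-true cast shadow), and place a
  person silhouette of opposite hue with per-pixel random value texture
  (gradients uncorrelated with the background). Black and white anchor
  patches identical in both frames pin the value normalization so the
  shadow's normalized ratio equals ρ up to quantization.

What these fixtures do *not* emulate: real cast-shadow penumbra and soft
edges, JPEG/ISO noise, illumination drift, non-rigid clothing deformation,
occlusion by furniture, camera perspective foreshortening, and multiple
people. Passing the suite therefore demonstrates the pipeline's logic —
thresholds, geometry, timing — under controlled conditions, not performance
on real footage.

## Problem sizes and determinism

The shipped checks use sizes chosen to characterize behaviour well at
interactive cost: 100 silhouettes for conservation, 50 shapes ≤ 128² for
oracle equivalence, 20 shadow scenes (96×128), 400 silhouettes per class for
10-fold cross-validation, and 60 scripted sequences (20 falls with
transitions 11–24, 20 slow-lie with 80–118, 10 walk + 10 sit) for end-to-end
discrimination. All randomness flows from explicit seeds; identical seeds
reproduce results bit-for-bit.

## Known limitations

* The median background model has no update mechanism; moved furniture
  remains foreground until retraining (the blob scorer usually ignores it,
  but it can steal the selection if the person is off-screen).
* Descriptor aliasing for very small silhouettes (above).
* The motion/settledness epsilons are calibrated for silhouette flicker of
  a few percent; extremely noisy segmentation would need larger values and
  correspondingly longer inactivity windows.
* The rule engine assumes one person; a second moving person corrupts both
  blob selection and the transition clock.
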