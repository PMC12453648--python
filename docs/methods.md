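# Methods

## Model

The network is a single-stage, detector-style segmentation model: a
residual convolutional backbone at full resolution, a five-branch
multi-scale fusion block, sequential spatial and channel attention,
and three parallel per-pixel heads (class softmax, objectness sigmoid,
box regression). It assumes RGB inputs in [0, 1] with height and width
divisible by 4 (the two stride-2 stages); `predict()` reflect-pads
other sizes and crops the result.

Design choices where the architecture was genuinely open:

* **Backbone.** A generic residual stack (Conv-BN-SiLU, additive
  skips) rather than any specific published detector backbone; the
  approach constrains the backbone only to be detector-like and
  residual. Width and depth are configuration (`base_width`,
  `backbone_depth`), defaulting to 32/4 — sized for CPU-scale runs.
* **Branch alignment.** The five scale branches have different
  strides; before concatenation all are bilinearly resampled to the
  backbone's stride-1 resolution, so the heads keep full resolution.
* **Resampling modes.** Downsampling is a stride-2 convolution by
  default, or 2×2 max-pooling; upsampling is bilinear by default, or a
  learned alternative implemented as zero-insertion upsampling
  followed by a 3×3 convolution (a stride-2 transposed convolution in
  factored form).
* **Spatial-attention padding.** The 7×7 attention convolution uses
  reflect padding so that a spatially constant feature map yields a
  spatially constant attention map; zero padding would inject edge
  artefacts into the gate.
* **Box decoding.** Anchor-free: every pixel with objectness > 0.5
  proposes the box regressed at that pixel (class = foreground argmax
  there), followed by greedy per-class NMS at IoU 0.5, capped at the
  top 200 candidates by objectness.
* **Unused branches are not instantiated.** With
  `disable_multiscale` the fused map is a 1×1 projection of the
  backbone output; with `disable_attention` the fused map feeds the
  heads directly. Only the parameters of active branches exist, so
  every parameter participates in every forward pass.

## Loss

L = λ_cls·L_cls + λ_IoU·L_IoU + λ_box·L_box + λ_obj·L_obj, defaults
λ = (1, 1, 0.5, 1). The λ's are fixed configuration; class-level
adaptivity is carried entirely by the class weights, which are
computed once from the training split.

* **Class weights.** w_k = 1/(N_k + ε), ε = 10⁻⁶, normalized to mean 1
  so the loss scale is dataset-independent. The weight appears exactly
  once, inside the focal term; applying it a second time at
  aggregation would square it and blow up rare-class gradients.
* **Classification.** Mean over *all* pixels of
  −w_{k*}(1 − p_{k*})^γ log p_{k*} at the true class k*, γ = 2,
  probabilities clamped at 10⁻⁷. Averaging over all pixels (rather
  than foreground only) keeps background calibrated; the weights
  already discount its dominance.
* **Soft IoU.** Σ(p·g) / (Σp + Σg − Σ(p·g)) on the predicted
  probability map of one class against its binary ground truth;
  differentiable during training, exact set IoU on hard labels. Two
  empty masks score 1 by convention. L_IoU averages (1 − IoU) over the
  foreground classes present in the ground truth — a per-class rather
  than per-instance or global choice, isolated in one function.
* **Boxes.** Ground-truth boxes are tight axis-aligned rectangles
  around 8-connected components of each non-background class
  (components under 16 px are treated as annotation specks). Each GT
  box is greedily matched to the same-class decoded prediction with
  highest IoU ≥ 0.3, each prediction used once; matched pairs
  contribute the squared coordinate error, unmatched GT boxes the
  loss of the zero box (a constant — the box head therefore starts
  learning once objectness clears the decode threshold, which happens
  within a few epochs).
* **Objectness.** Per-pixel binary cross-entropy against the binary
  foreground map, probabilities clamped to [10⁻⁷, 1 − 10⁻⁷].

## Training protocol

Adam, initial learning rate 10⁻³, batch size 16, at most 100 epochs.
One monitored quantity — validation total loss — drives both the
schedule (× 0.1 after 5 consecutive epochs without improvement) and
early stopping (after 10); "improvement" is a strict decrease beyond
10⁻⁸, and counters reset on any improvement. The best checkpoint is
the lowest-validation-loss epoch. Epoch order is reshuffled from an
epoch-derived seed; optional horizontal-flip augmentation is off by
default. All computation is NumPy, so runs are deterministic given the
seed and bit-identical on re-execution.

## Numerical core

`lapseg.nn` is a tape-based reverse-mode autodiff engine over float32
NumPy arrays. Convolution is im2col + GEMM; its input gradient is the
stride-dilated output gradient fully correlated with the flipped
kernel. Max-based operations (max-pool, channel/global max) route
gradients to the first argmax. Bilinear resampling is a separable
linear map whose backward applies the transposed interpolation
matrices. Every primitive is checked against central finite
differences in the test suite; max-like ops are checked on inputs with
pairwise gaps larger than the perturbation so tie-switching cannot
corrupt the comparison.

## Synthetic scenes

The generator reproduces the statistical structure of laparoscopic
frames, not their appearance: one dominant organ-like blob (a
perturbed ellipse, target 35% of pixels), a small minority blob seeded
on the dominant blob's boundary (2%, the way the gallbladder abuts the
liver), and 1–2 thin rotated bars (5%, width 2–5 px) drawn last so
they overwrite organ pixels as instruments occlude tissue. Images are
per-class base colors plus a smooth luminance texture and Gaussian
noise (σ = 0.03). The minority class's color is deliberately close to
the dominant organ's: a partly obscured gallbladder is liver-toned,
and with a clearly distinct color per-pixel classification would be
trivially solvable from color alone, leaving nothing for class
weighting to demonstrate. Frequencies are targets, not constraints —
shapes are placed by area budget and the realized mask is accepted;
empirically the 200-scene mean frequencies land within ±30% of target.

Scenes are deterministic given (seed, index) via an independent stream
keyed by `seed XOR index`. What the generator does *not* emulate:
photorealistic texture, specular highlights, smoke, camera motion,
inter-frame correlation, more than one instance of the minority organ.
Tests passing on these scenes show the pipeline is correct and that
balancing helps under controlled imbalance; they do not certify
real-data accuracy.

## Evaluation

Per-class precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R),
IoU = TP/(TP+FP+FN), micro-aggregated: confusions are summed over all
test pixels first, metrics computed once. A class absent from both
prediction and ground truth has undefined metrics, reported as NA and
excluded from macro means; background appears in the table but not in
the headline (foreground) macro mean. Micro-aggregation and the NA
convention are documented choices where reporting conventions differ.

## Reference experiments

* **Overfit sanity** — base_width 32 / depth 4 on a single 64×64
  scene used as train and validation set must reach macro IoU ≥ 0.95
  within 300 Adam steps (typically ~40). Failure indicates a broken
  gradient path, not a tuning problem.
* **Balancing efficacy** — 200 scenes (120/40/40 split), minority
  class at 2% of pixels; each arm trained for 2 epochs of 15 batches
  of 8 (two passes over the training scenes, deliberately far from
  convergence) across 5 seeds. The adaptive class-balancing loss must
  give a strictly higher median minority-class test IoU than uniform
  weights with γ = 0. The budget matters: at convergence both arms
  solve these scenes and the comparison measures nothing; the effect
  of balancing is to pull the minority class forward in training.
  Problem sizes throughout (64×64 scenes, tiny widths) are chosen so
  the full suite runs on one CPU in minutes.

## Known limitations

* The λ weights of the composite loss are fixed; no update rule is
  implemented (they are logged per epoch so one can be added).
* Box supervision is weak early in training by construction (constant
  loss for unmatched boxes).
* The engine is single-threaded NumPy; it is sized for 64×64 desk
  experiments, not 854×480 production training.
* Whether instrument classes should receive boxes is unsettled in the
  source material; boxes are derived for all non-background classes.
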