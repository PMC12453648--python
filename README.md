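# lapseg

Semantic segmentation of laparoscopic surgical scenes with a
detector-style network and an adaptive class-balancing loss.

## The problem

Laparoscopic cholecystectomy video frames contain a few large
structures (liver, abdominal wall, background) and several small but
clinically critical ones (gallbladder, cystic duct, vessels), with thin
surgical instruments occluding everything. Pixel counts are therefore
heavily imbalanced: an unweighted per-pixel loss is dominated by the
large classes and under-trains the rare ones. `lapseg` implements a
segmentation network aimed at this regime, plus the data handling
around it: CholecSeg8k-layout readers with strict case-wise
(per-video) splits, a seeded synthetic-scene generator reproducing the
imbalance structure, a training loop, and per-class evaluation.

Because no GPU deep-learning framework is assumed, the network runs on
a compact NumPy reverse-mode autodiff engine (`lapseg.nn`) whose
primitives (conv2d, pooling, bilinear resampling, batch norm, softmax)
are finite-difference gradient-checked in the test suite.

## The model

An input image **I** ∈ ℝ^{H×W×3} passes through:

1. **Residual backbone** — Conv-BN-SiLU blocks with additive skips at
   full resolution, producing F at stride 1.
2. **Multi-scale fusion** — two downsampling stages give F_d1 (stride
   2) and F_d2 (stride 4); upsampling restores F_u1, F_u2. All five
   branches are resampled to stride 1, concatenated, and fused by a
   1×1 convolution: F_final = Conv₁ₓ₁([F, F_d1, F_d2, F_u1, F_u2]).
3. **Sequential attention** — a spatial gate
   A_sp = σ(Conv₇ₓ₇([AvgPool_ch, MaxPool_ch])) multiplies F_final;
   then a channel gate A_ch = σ(FC₂(ReLU(FC₁(V_avg + V_max)))) with a
   reduction-ratio-r bottleneck multiplies the result.
4. **Parallel heads** — per-pixel class probabilities P(x,y,k)
   (softmax), objectness S(x,y) (sigmoid) and normalized box
   coordinates (x, y, w, h). The final label at each pixel is the
   argmax of P(x,y,k)·S(x,y) for foreground k and P(x,y,0)·(1−S(x,y))
   for background.

Training minimises L = λ_cls·L_cls + λ_IoU·L_IoU + λ_box·L_box +
λ_obj·L_obj where

* L_cls is a class-weighted focal loss, mean over pixels of
  −w_k (1−p)^γ log p at the true class, with w_k = 1/(N_k+ε)
  normalized to mean 1 (N_k = training-set pixel count of class k);
* L_IoU = mean over foreground classes of (1 − softIoU), with
  softIoU = Σp·g / (Σp + Σg − Σp·g);
* L_box is the mean squared coordinate error over greedily matched
  ground-truth/predicted boxes (boxes are derived from masks as tight
  rectangles around 8-connected components);
* L_obj is per-pixel binary cross-entropy on objectness.

Protocol: Adam (lr 10⁻³), LR × 0.1 after 5 epochs without validation
improvement, early stop after 10, at most 100 epochs, batch size 16.

## Worked example

```python
from lapseg import NetworkConfig, TrainConfig, train
from lapseg.network import MultiScaleAttentionNet
from lapseg.synthetic import SceneSpec, generate_dataset
from lapseg.metrics import macro_means

scenes = generate_dataset(SceneSpec(seed=0), 60)   # 64x64, 4 classes
cfg = NetworkConfig(num_classes=4, base_width=16, backbone_depth=2,
                    fused_channels=32, channel_reduction_ratio=8, init_seed=0)
model = MultiScaleAttentionNet(cfg)
res = train(model, scenes[:40], scenes[40:50],
            TrainConfig(max_epochs=6, batch_size=8, seed=0))
print(res.summary())
table = res.evaluate(scenes[50:])
print(table[["class_name", "precision", "recall", "f1", "iou"]].round(3))
print(macro_means(table).round(3))
```

prints (exact output of this snippet):

```
Segmentation network fit
==========================================================
epochs run:        6 (cap 6)
best epoch:        5
best val loss:     0.990651
final lr:          1.00e-03
class balancing:   on (gamma=2.0)
class weights:     [0.08, 0.16, 2.68, 1.08]
----------------------------------------------------------
last epoch: l_cls=0.0425, l_iou=0.7968, l_box=0.4369, l_obj=0.0988, l_total=1.1566

 class_id class_name  precision  recall    f1   iou
        0    class_0      0.981   0.980 0.981 0.962
        1    class_1      0.962   0.928 0.945 0.896
        2    class_2      0.461   0.397 0.426 0.271
        3    class_3      0.698   0.927 0.796 0.661
```

The class-weight vector shows the inverse-frequency balancing at work:
the minority "gallbladder-like" class (2% of pixels) carries weight
2.68 against 0.08 for background. After six epochs the dominant organ
reaches IoU 0.90 while the minority class sits at 0.27 — rare classes
are learned last, which is exactly the regime the balancing loss
targets (see `lapseg.experiments.balancing_efficacy` for the
controlled comparison).

## Command line

```sh
lapseg generate-data --n 50 --out data/ --seed 7     # synthetic PNGs
lapseg train --config cfg.yaml                       # checkpoint + history
lapseg evaluate --checkpoint run/checkpoint.npz --data data/ \
       --class-map identity:4 --subset all --plot metrics.png
lapseg predict --checkpoint run/checkpoint.npz --image frame.png --out mask.png
lapseg ablate --config cfg.yaml --arms no_multiscale,no_attention,no_balancing
```

For real CholecSeg8k data, point `data.root` at the dataset directory;
the shipped class map (`lapseg/data/cholecseg8k_classes.yaml`, 13
classes) and the per-video train/val/test assignment
(`lapseg.dataset_io.CHOLECSEG8K_SPLIT`) are used by default, so frames
from one surgical case never leak across subsets.

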