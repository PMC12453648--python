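"""Training loop: Adam, reduce-LR-on-plateau, early stopping.

Protocol: Adam at initial learning rate 1e-3; the learning rate is
multiplied by 0.1 when the validation loss has not improved for five
consecutive epochs; training stops when it has not improved for ten
consecutive epochs or at the epoch cap (100). The best checkpoint is
the one with the lowest validation loss. Both the schedule and the
stopping rule monitor the same quantity (validation total loss);
improvement means a strict decrease of more than 1e-8.

Data are (image, mask) pairs in memory; epoch order is reshuffled from
an epoch-derived seed so runs are reproducible end to end.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from .dataset_io import boxes_from_mask, class_pixel_counts_from_masks
from .metrics import evaluate_masks, macro_means
from .network import (
    HeadOutputs,
    MultiScaleAttentionNet,
    NetworkConfig,
    box_iou,
    decode_boxes,
    final_segmentation,
)
from .nn import Adam, pixel_gather


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-3
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    improvement_threshold: float = 1e-8
    loss: L.LossWeights = field(default_factory=L.LossWeights)
    class_balancing: bool = True      # False: uniform weights (gamma from loss cfg)
    min_box_area: int = 16
    box_match_iou: float = 0.3
    steps_per_epoch: int | None = None  # cap for micro-training runs
    augment_hflip: bool = False
    target_val_iou: float | None = None  # optional stop for overfit diagnostics

    def __post_init__(self):
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class PlateauTracker:
    """Shared improvement bookkeeping for the LR schedule and stopping."""

    def __init__(self, patience: int, threshold: float = 1e-8):
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.bad = 0

    def update(self, value: float) -> bool:
        """Record one epoch; True when `patience` epochs passed without
        improvement (the counter then resets)."""
        if value < self.best - self.threshold:
            self.best = value
            self.bad = 0
            return False
        self.bad += 1
        if self.bad >= self.patience:
            self.bad = 0
            return True
        return False


def lr_on_plateau(val_losses, cfg: TrainConfig, lr0: float | None = None) -> float:
    """Learning rate after observing a validation-loss history."""
    lr = cfg.lr0 if lr0 is None else lr0
    tracker = PlateauTracker(cfg.plateau_patience, cfg.improvement_threshold)
    for v in val_losses:
        if tracker.update(v):
            lr *= cfg.plateau_factor
    return lr


# ---------------------------------------------------------------------------
# loss assembly
# ---------------------------------------------------------------------------

def _match_boxes(out: HeadOutputs, gt_boxes_batch, match_iou: float):
    """Greedy per-image matching of ground-truth boxes to decoded
    predictions of the same class (best IoU >= threshold, each
    prediction used once). Returns (matched pred-pixel refs, gt arrays,
    unmatched gt arrays)."""
    preds = decode_boxes(out)
    matched_px, matched_gt, unmatched = [], [], []
    used = set()
    for n, gt_boxes in enumerate(gt_boxes_batch):
        cands = [p for p in preds if p["n"] == n]
        for gb in gt_boxes:
            k, coords = gb[0], np.asarray(gb[1:], dtype=np.float32)
            best, best_iou = None, match_iou
            for i, p in enumerate(cands):
                if id(p) in used or p["class_id"] != k:
                    continue
                iou = box_iou(p["box"], coords)
                if iou >= best_iou:
                    best, best_iou = p, iou
            if best is None:
                unmatched.append(coords)
            else:
                used.add(id(best))
                matched_px.append((best["n"], best["y"], best["x"]))
                matched_gt.append(coords)
    return matched_px, matched_gt, unmatched


def compute_batch_loss(out: HeadOutputs, masks: np.ndarray, gt_boxes_batch,
                       weights: L.ClassWeights, lw: L.LossWeights,
                       match_iou: float = 0.3) -> L.LossBreakdown:
    """The four-term composite loss for one forward pass."""
    l_cls = L.classification_loss(out.p_cls, masks, weights, lw.gamma)
    l_iou = L.iou_loss(L.soft_iou_per_class(out.p_cls, masks))
    y_obj = (masks > 0).astype(np.float32)[:, None]
    l_obj = L.objectness_loss(out.s_obj, y_obj)
    matched_px, matched_gt, unmatched = _match_boxes(out, gt_boxes_batch, match_iou)
    if matched_px:
        n_i, y_i, x_i = zip(*matched_px)
        pred_rows = pixel_gather(out.b_map, n_i, y_i, x_i)  # (M,4)
        d = pred_rows - L.Tensor(np.stack(matched_gt))
        l_box_matched = (d * d).sum(axis=1)
        total = l_box_matched.sum()
        count = len(matched_px)
    else:
        total = L.Tensor(0.0)
        count = 0
    for g in unmatched:
        total = total + float((g ** 2).sum())
        count += 1
    l_box = total * (1.0 / count) if count else L.Tensor(0.0)
    return L.total_loss(l_cls, l_iou, l_box, l_obj, lw)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    """Fitted-model results: best weights, history and diagnostics."""

    model: MultiScaleAttentionNet
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    class_weights: L.ClassWeights
    config: TrainConfig

    def evaluate(self, pairs, class_names=None) -> pd.DataFrame:
        self.model.eval()
        k = self.model.cfg.num_classes
        preds = ((self.model.predict(img), mask) for img, mask in pairs)
        return evaluate_masks(preds, k, class_names)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Segmentation network fit",
            "=" * 58,
            f"epochs run:        {len(h)} (cap {self.config.max_epochs})",
            f"best epoch:        {self.best_epoch}",
            f"best val loss:     {self.best_val_loss:.6f}",
            f"final lr:          {h['lr'].iloc[-1]:.2e}",
            f"class balancing:   {'on' if self.config.class_balancing else 'off'}"
            f" (gamma={self.config.loss.gamma})",
            f"class weights:     "
            + np.array2string(np.asarray(self.class_weights.normalized),
                              precision=3, separator=", "),
            "-" * 58,
            "last epoch: "
            + ", ".join(f"{k}={h[k].iloc[-1]:.4f}"
                        for k in ("l_cls", "l_iou", "l_box", "l_obj", "l_total")),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_seed(seed: int, epoch: int) -> int:
    return (seed * 1000003 + epoch) % (2 ** 31)


def _stack_batch(pairs):
    imgs = np.stack([np.transpose(p[0], (2, 0, 1)) for p in pairs]).astype(np.float32)
    masks = np.stack([p[1] for p in pairs])
    return imgs, masks


def train(model: MultiScaleAttentionNet, train_data, val_data,
          cfg: TrainConfig) -> TrainResult:
    """Fit the network; returns a results object with the best weights
    loaded into `model`."""
    train_data = list(train_data)
    val_data = list(val_data)
    if not train_data or not val_data:
        raise ValueError("train and val data must be non-empty")
    k = model.cfg.num_classes

    if cfg.class_balancing:
        counts = class_pixel_counts_from_masks((m for _, m in train_data), k)
        weights = L.ClassWeights.from_counts(counts)
    else:
        weights = L.ClassWeights.uniform(k)

    gt_boxes = [boxes_from_mask(m, cfg.min_box_area) for _, m in train_data]
    val_boxes = [boxes_from_mask(m, cfg.min_box_area) for _, m in val_data]

    opt = Adam(model.parameters(), lr=cfg.lr0)
    lr_tracker = PlateauTracker(cfg.plateau_patience, cfg.improvement_threshold)
    stop_tracker = PlateauTracker(cfg.early_stop_patience, cfg.improvement_threshold)
    best_state, best_val, best_epoch = None, np.inf, -1
    rows = []

    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        rng = np.random.default_rng(_epoch_seed(cfg.seed, epoch))
        order = rng.permutation(len(train_data))
        model.train()
        sums = {"l_cls": 0.0, "l_iou": 0.0, "l_box": 0.0, "l_obj": 0.0, "l_total": 0.0}
        nb = 0
        for start in range(0, len(order), cfg.batch_size):
            if cfg.steps_per_epoch is not None and nb >= cfg.steps_per_epoch:
                break
            idx = order[start:start + cfg.batch_size]
            batch = [train_data[i] for i in idx]
            boxes = [gt_boxes[i] for i in idx]
            if cfg.augment_hflip:
                flip = rng.random(len(batch)) < 0.5
                batch = [(img[:, ::-1].copy(), m[:, ::-1].copy()) if f else (img, m)
                         for (img, m), f in zip(batch, flip)]
                boxes = [[(k_, 1 - xc, yc, w, h) for k_, xc, yc, w, h in bs] if f else bs
                         for bs, f in zip(boxes, flip)]
            imgs, masks = _stack_batch(batch)
            out = model(imgs)
            try:
                lb = compute_batch_loss(out, masks, boxes, weights, cfg.loss,
                                        cfg.box_match_iou)
            except FloatingPointError as e:
                raise FloatingPointError(
                    f"{e} (epoch {epoch}, batch {nb})"
                ) from None
            opt.zero_grad()
            lb.total.backward()
            opt.step()
            for name in sums:
                sums[name] += getattr(lb, name)
            nb += 1

        val_loss = validation_loss(model, val_data, val_boxes, weights, cfg)

        model.eval()
        val_iou = float(macro_means(evaluate_masks(
            ((final_segmentation(model(_stack_batch([p])[0]))[0], p[1])
             for p in val_data), k))["iou"])

        if val_loss < best_val - cfg.improvement_threshold:
            best_val, best_epoch = val_loss, epoch
            best_state = copy.deepcopy(model.state_dict())
        if lr_tracker.update(val_loss):
            opt.lr *= cfg.plateau_factor
        stop = stop_tracker.update(val_loss)
        rows.append({
            "epoch": epoch, **{n: s / max(nb, 1) for n, s in sums.items()},
            "val_loss": val_loss, "val_macro_iou": val_iou,
            "lr": opt.lr, "seconds": time.time() - t0,
        })
        if stop:
            break
        if cfg.target_val_iou is not None and val_iou >= cfg.target_val_iou:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_loss=float(best_val),
                       class_weights=weights, config=cfg)


def validation_loss(model, val_data, val_boxes, weights, cfg: TrainConfig) -> float:
    model.eval()
    total, n = 0.0, 0
    for start in range(0, len(val_data), cfg.batch_size):
        batch = val_data[start:start + cfg.batch_size]
        boxes = val_boxes[start:start + cfg.batch_size]
        imgs, masks = _stack_batch(batch)
        out = model(imgs)
        lb = compute_batch_loss(out, masks, boxes, weights, cfg.loss,
                                cfg.box_match_iou)
        total += lb.l_total * len(batch)
        n += len(batch)
    return total / n


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

ABLATION_ARMS = ("no_multiscale", "no_attention", "no_balancing")


def _data_fingerprint(pairs) -> str:
    h = 0
    for img, mask in pairs:
        h = (h * 1000003 + int(np.float64(img).sum() * 1e6) + int(mask.sum())) % (2 ** 61)
    return f"{h:016x}"


def run_ablation(net_cfg: NetworkConfig, train_cfg: TrainConfig,
                 train_data, val_data, test_data, arms=ABLATION_ARMS) -> dict:
    """Train the full model and each requested ablation arm on identical
    data and seed; returns {arm: {"metrics": table, "result": TrainResult,
    "fingerprint": str}}."""
    bad = set(arms) - set(ABLATION_ARMS)
    if bad:
        raise ValueError(f"unknown ablation arms: {sorted(bad)}")
    fingerprint = _data_fingerprint(train_data)
    out = {}
    for arm in ("full", *arms):
        ncfg, tcfg = net_cfg, train_cfg
        if arm == "no_multiscale":
            ncfg = replace(net_cfg, disable_multiscale=True)
        elif arm == "no_attention":
            ncfg = replace(net_cfg, disable_attention=True)
        elif arm == "no_balancing":
            tcfg = replace(train_cfg, class_balancing=False,
                           loss=replace(train_cfg.loss, gamma=0.0))
        model = MultiScaleAttentionNet(ncfg)
        res = train(model, train_data, val_data, tcfg)
        out[arm] = {
            "metrics": res.evaluate(test_data),
            "result": res,
            "fingerprint": fingerprint,
        }
    return out
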