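"""The adaptive class-balancing loss system.

Class weights are inversely proportional to training-set pixel
frequency, w_k = 1/(N_k + eps), normalized to mean 1 so the loss scale
is comparable across datasets. The classification term is a focal loss
-(w_k)(1-p)^gamma log p evaluated at each pixel's true class: the class
weight rebalances rare classes, the focusing term down-weights easy
pixels. The weight is applied exactly once, inside the focal term;
applying it again at aggregation would square it and destabilise rare
classes. The remaining terms are a soft (probability-mass) IoU
complement per foreground class, a squared-coordinate box regression
penalty, and per-pixel binary cross-entropy on objectness; the total is
their lambda-weighted sum.

All differentiable terms accept either autodiff Tensors (training) or
plain arrays (analytic evaluation); scalars come back as floats via
``.item()`` on the returned Tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, gather_channel

P_CLAMP = 1e-7


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


# ---------------------------------------------------------------------------
# class weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeights:
    raw: np.ndarray         # 1/(N_k + eps)
    normalized: np.ndarray  # scaled to mean 1
    epsilon: float

    @classmethod
    def from_counts(cls, counts, eps: float = 1e-6) -> "ClassWeights":
        counts = np.asarray(counts, dtype=np.float64)
        if (counts < 0).any():
            raise ValueError("pixel counts must be non-negative")
        if eps <= 0:
            raise ValueError("eps must be positive")
        raw = 1.0 / (counts + eps)
        normalized = raw * (len(raw) / raw.sum())
        return cls(raw=raw, normalized=normalized, epsilon=eps)

    @classmethod
    def uniform(cls, k: int) -> "ClassWeights":
        ones = np.ones(k)
        return cls(raw=ones.copy(), normalized=ones, epsilon=1e-6)


@dataclass(frozen=True)
class LossWeights:
    lambda_cls: float = 1.0
    lambda_iou: float = 1.0
    lambda_box: float = 0.5
    lambda_obj: float = 1.0
    gamma: float = 2.0

    def __post_init__(self):
        for name in ("lambda_cls", "lambda_iou", "lambda_box", "lambda_obj", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def focal_term(p, w, gamma: float):
    """-w (1-p)^gamma log p, with p clamped away from 0."""
    p = np.clip(np.asarray(p, dtype=np.float64), P_CLAMP, 1.0)
    return -w * (1.0 - p) ** gamma * np.log(p)


def classification_loss(p_cls, gt, weights: ClassWeights | None = None,
                        gamma: float = 2.0) -> Tensor:
    """Mean over all pixels of the focal term at the true class.

    p_cls: (N,K,H,W) probabilities (Tensor or array); gt: (N,H,W) or
    (H,W) integer labels.
    """
    p_cls = _as_tensor(p_cls)
    gt = np.asarray(gt, dtype=np.int64)
    if gt.ndim == 2:
        gt = gt[None]
    if p_cls.ndim != 4 or p_cls.shape[0] != gt.shape[0] or p_cls.shape[2:] != gt.shape[1:]:
        raise ValueError(f"shape mismatch: p_cls {p_cls.shape} vs gt {gt.shape}")
    k = p_cls.shape[1]
    if gt.max() >= k:
        raise ValueError("ground-truth label out of range")
    wvec = np.ones(k) if weights is None else weights.normalized
    wmap = wvec[gt][:, None].astype(np.float32)  # (N,1,H,W), constant
    p = gather_channel(p_cls, gt).clip(P_CLAMP, 1.0)
    loss = Tensor(wmap) * ((1.0 - p) ** gamma) * (-(p.log()))
    return loss.mean()


def soft_iou(pred, gt) -> Tensor:
    """Probability-mass IoU: sum(p*g) / (sum p + sum g - sum(p*g)).

    With binary inputs this is exact set IoU; with probabilities it is
    the differentiable relaxation used during training. Two empty masks
    have IoU 1 by convention.
    """
    pred = _as_tensor(pred)
    g = Tensor(np.asarray(gt, dtype=np.float32))
    inter = (pred * g).sum()
    union = pred.sum() + g.sum() - inter
    if float(union.data) <= 0.0:
        return Tensor(1.0)
    return inter / union


def soft_iou_per_class(p_cls, gt) -> dict:
    """Soft IoU of each foreground class present in the ground truth.

    Returns {class_id: Tensor}. Classes absent from the ground truth are
    skipped; the IoU-loss averages only over what is annotated.
    """
    p_cls = _as_tensor(p_cls)
    gt = np.asarray(gt, dtype=np.int64)
    if gt.ndim == 2:
        gt = gt[None]
    out = {}
    for k in np.unique(gt):
        if k == 0:
            continue
        pk = gather_channel(p_cls, np.full_like(gt, k))
        out[int(k)] = soft_iou(pk, (gt == k)[:, None])
    return out


def iou_loss(ious) -> Tensor:
    """Mean of (1 - IoU) over foreground classes present in the ground
    truth; 0 when none are present."""
    vals = list(ious.values()) if isinstance(ious, dict) else list(ious)
    if not vals:
        return Tensor(0.0)
    total = None
    for v in vals:
        v = _as_tensor(v)
        total = v if total is None else total + v
    return 1.0 - total * (1.0 / len(vals))


def box_loss(b_pred, b_gt) -> Tensor:
    """Sum of squared differences over the 4 box coordinates."""
    d = _as_tensor(b_pred) - _as_tensor(np.asarray(b_gt, dtype=np.float32))
    return (d * d).sum()


def box_regression_loss(matched_pairs, unmatched_gt=()) -> Tensor:
    """Mean pairwise box loss; each unmatched ground-truth box counts as
    being predicted by the zero box."""
    terms = [box_loss(p, g) for p, g in matched_pairs]
    terms += [box_loss(np.zeros(4, dtype=np.float32), g) for g in unmatched_gt]
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def objectness_loss(s_obj, y_obj) -> Tensor:
    """Mean binary cross-entropy between objectness map and the binary
    foreground map."""
    s = _as_tensor(s_obj).clip(P_CLAMP, 1.0 - P_CLAMP)
    y = Tensor(np.asarray(y_obj, dtype=np.float32))
    if s.shape != y.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {y.shape}")
    bce = -(y * s.log() + (1.0 - y) * (1.0 - s).log())
    return bce.mean()


# ---------------------------------------------------------------------------
# composite
# ---------------------------------------------------------------------------

@dataclass
class LossBreakdown:
    l_cls: float
    l_iou: float
    l_box: float
    l_obj: float
    l_total: float
    total: Tensor | None = None  # differentiable total when built from Tensors


def total_loss(l_cls, l_iou, l_box, l_obj, lw: LossWeights) -> LossBreakdown:
    parts = {"l_cls": l_cls, "l_iou": l_iou, "l_box": l_box, "l_obj": l_obj}
    for name, part in parts.items():
        val = float(part.data) if isinstance(part, Tensor) else float(part)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component: {name}")
    t = (lw.lambda_cls * _as_tensor(l_cls) + lw.lambda_iou * _as_tensor(l_iou)
         + lw.lambda_box * _as_tensor(l_box) + lw.lambda_obj * _as_tensor(l_obj))
    return LossBreakdown(
        l_cls=float(_as_tensor(l_cls).data),
        l_iou=float(_as_tensor(l_iou).data),
        l_box=float(_as_tensor(l_box).data),
        l_obj=float(_as_tensor(l_obj).data),
        l_total=float(t.data),
        total=t,
    )
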