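"""The segmentation network.

Forward graph: a residual detector-style backbone produces a stride-1
feature map; two successive downsampling stages and their upsampled
counterparts give five feature branches that are resampled to the
backbone resolution, concatenated, and fused by a 1x1 convolution.
Sequential spatial then channel attention gates the fused features, and
three parallel 1x1 heads emit per-pixel class probabilities (softmax),
an objectness map (sigmoid) and normalized box coordinates (sigmoid).
The final label map multiplies class probability by objectness for
foreground classes and by (1 - objectness) for background, then takes
the per-pixel argmax.

Every architectural contribution is toggleable (`disable_multiscale`,
`disable_attention`, `residual`) so ablation arms are structural
variants of one model rather than separate implementations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    ConvBlock,
    Linear,
    Module,
    ResidualBlock,
    Tensor,
    concat,
    max_pool2x2,
    resize_bilinear,
    softmax,
    zero_upsample2x,
)


@dataclass(frozen=True)
class NetworkConfig:
    num_classes: int = 4
    in_channels: int = 3
    base_width: int = 32
    backbone_depth: int = 4
    fused_channels: int = 64
    channel_reduction_ratio: int = 16
    spatial_kernel: int = 7
    upsample_mode: str = "bilinear"          # or "transposed_conv"
    downsample_mode: str = "strided_conv"    # or "max_pool"
    disable_multiscale: bool = False
    disable_attention: bool = False
    residual: bool = True
    init_seed: int = 0

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.fused_channels % self.channel_reduction_ratio:
            raise ValueError("channel_reduction_ratio must divide fused_channels")
        if self.upsample_mode not in ("bilinear", "transposed_conv"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.downsample_mode not in ("strided_conv", "max_pool"):
            raise ValueError(f"unknown downsample_mode {self.downsample_mode!r}")
        for name in ("num_classes", "in_channels", "base_width", "backbone_depth",
                     "fused_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        import yaml

        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        return cls(**doc)


@dataclass
class AttentionOutputs:
    a_spatial: Tensor | None = None   # (N,1,H,W) in (0,1)
    a_channel: Tensor | None = None   # (N,C) in (0,1)
    v_avg: Tensor | None = None       # (N,C)
    v_max: Tensor | None = None       # (N,C)


@dataclass
class HeadOutputs:
    p_cls: Tensor                     # (N,K,H,W), softmax over K
    s_obj: Tensor                     # (N,1,H,W), sigmoid
    b_map: Tensor                     # (N,4,H,W), sigmoid-normalized (xc,yc,w,h)
    attention: AttentionOutputs = field(default_factory=AttentionOutputs)
    features: dict = field(default_factory=dict)


class _Downsample(Module):
    def __init__(self, ch, mode, rng):
        super().__init__()
        self.mode = mode
        if mode == "strided_conv":
            self.block = ConvBlock(ch, ch, kernel=3, stride=2, rng=rng)

    def __call__(self, x):
        if self.mode == "strided_conv":
            return self.block(x)
        return max_pool2x2(x)


class _Upsample(Module):
    """Restore spatial resolution by `stages` factor-2 steps."""

    def __init__(self, ch, stages, mode, rng):
        super().__init__()
        self.mode = mode
        self.stages = stages
        if mode == "transposed_conv":
            self.blocks = [ConvBlock(ch, ch, kernel=3, rng=rng) for _ in range(stages)]

    def __call__(self, x):
        if self.mode == "transposed_conv":
            for b in self.blocks:
                x = b(zero_upsample2x(x))
            return x
        n, c, h, w = x.shape
        return resize_bilinear(x, (h << self.stages, w << self.stages))


class MultiScaleAttentionNet(Module):
    """Residual backbone + five-branch fusion + dual attention + heads."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        w = cfg.base_width
        self.stem = ConvBlock(cfg.in_channels, w, rng=rng)
        self.blocks = [ResidualBlock(w, rng=rng, residual=cfg.residual)
                       for _ in range(cfg.backbone_depth)]
        # only the branches the config uses are instantiated, so every
        # parameter of the model participates in its forward pass
        if cfg.disable_multiscale:
            self.proj_conv = Conv2d(w, cfg.fused_channels, kernel=1, rng=rng)
        else:
            self.down1 = _Downsample(w, cfg.downsample_mode, rng)
            self.down2 = _Downsample(w, cfg.downsample_mode, rng)
            self.up1 = _Upsample(w, 1, cfg.upsample_mode, rng)
            self.up2 = _Upsample(w, 2, cfg.upsample_mode, rng)
            self.fuse_conv = Conv2d(5 * w, cfg.fused_channels, kernel=1, rng=rng)
        if not cfg.disable_attention:
            # reflect padding keeps the attention map constant on constant
            # inputs (zero padding would inject edge artefacts)
            self.spatial_conv = Conv2d(2, 1, kernel=cfg.spatial_kernel, rng=rng,
                                       pad_mode="reflect")
            hidden = cfg.fused_channels // cfg.channel_reduction_ratio
            self.fc1 = Linear(cfg.fused_channels, max(hidden, 1), rng=rng)
            self.fc2 = Linear(max(hidden, 1), cfg.fused_channels, rng=rng)
        self.cls_head = Conv2d(cfg.fused_channels, cfg.num_classes, kernel=1, rng=rng)
        self.obj_head = Conv2d(cfg.fused_channels, 1, kernel=1, rng=rng)
        self.box_head = Conv2d(cfg.fused_channels, 4, kernel=1, rng=rng)

    # -- pieces ---------------------------------------------------------------
    @staticmethod
    def _to_input(image) -> Tensor:
        """Accept (H,W,3), (N,H,W,3) or (N,C,H,W); return (N,C,H,W) Tensor."""
        if isinstance(image, Tensor):
            return image
        a = np.asarray(image, dtype=np.float32)
        if a.ndim == 3 and a.shape[-1] in (1, 3):
            a = a.transpose(2, 0, 1)[None]
        elif a.ndim == 4 and a.shape[-1] in (1, 3):
            a = a.transpose(0, 3, 1, 2)
        elif a.ndim == 3:
            a = a[None]
        return Tensor(a)

    def backbone_forward(self, image) -> Tensor:
        x = self._to_input(image)
        n, c, h, w = x.shape
        if h % 4 or w % 4:
            raise ValueError(
                f"input {h}x{w} not divisible by 4; pad the image first "
                "(predict() reflect-pads automatically)"
            )
        x = self.stem(x)
        for b in self.blocks:
            x = b(x)
        return x

    def multiscale_extract(self, f_yolo: Tensor):
        f_d1 = self.down1(f_yolo)
        f_d2 = self.down2(f_d1)
        f_u1 = self.up1(f_d1)
        f_u2 = self.up2(f_d2)
        return f_d1, f_d2, f_u1, f_u2

    def multiscale_fuse(self, f_yolo, f_d1, f_d2, f_u1, f_u2) -> Tensor:
        size = f_yolo.shape[2:]
        branches = [f_yolo] + [resize_bilinear(t, size) for t in (f_d1, f_d2, f_u1, f_u2)]
        f_multi = concat(branches, axis=1)
        if f_multi.shape[1] != self.fuse_conv.weight.shape[1]:
            raise ValueError("branch channel widths do not match the fusion conv")
        return self.fuse_conv(f_multi)

    def spatial_attention(self, f_final: Tensor):
        avg = f_final.mean(axis=1, keepdims=True)
        mx = f_final.max(axis=1, keepdims=True)
        a = self.spatial_conv(concat([avg, mx], axis=1)).sigmoid()
        return a, a * f_final

    def channel_attention(self, f_spatial: Tensor):
        n, c, h, w = f_spatial.shape
        flat = f_spatial.reshape(n, c, h * w)
        v_avg = flat.mean(axis=2)
        v_max = flat.max(axis=2)
        a = self.fc2(self.fc1(v_avg + v_max).relu()).sigmoid()  # (N,C)
        a4 = a.reshape(n, c, 1, 1)
        return AttentionOutputs(a_channel=a, v_avg=v_avg, v_max=v_max), a4 * f_spatial

    def heads_forward(self, f_channel: Tensor) -> HeadOutputs:
        p_cls = softmax(self.cls_head(f_channel), axis=1)
        s_obj = self.obj_head(f_channel).sigmoid()
        b_map = self.box_head(f_channel).sigmoid()
        return HeadOutputs(p_cls=p_cls, s_obj=s_obj, b_map=b_map)

    # -- full pass ------------------------------------------------------------
    def forward(self, image) -> HeadOutputs:
        f_yolo = self.backbone_forward(image)
        if self.cfg.disable_multiscale:
            f_final = self.proj_conv(f_yolo)
        else:
            f_final = self.multiscale_fuse(f_yolo, *self.multiscale_extract(f_yolo))
        if self.cfg.disable_attention:
            att = AttentionOutputs()
            f_channel = f_final
        else:
            a_spatial, f_spatial = self.spatial_attention(f_final)
            att, f_channel = self.channel_attention(f_spatial)
            att.a_spatial = a_spatial
        out = self.heads_forward(f_channel)
        out.attention = att
        out.features = {"f_yolo": f_yolo, "f_final": f_final, "f_channel": f_channel}
        return out

    __call__ = forward

    def predict(self, image) -> np.ndarray:
        """Label mask for one (H,W,3) image; reflect-pads to a multiple
        of 4 and crops back."""
        self.eval()
        a = np.asarray(image, dtype=np.float32)
        h, w = a.shape[:2]
        ph, pw = (-h) % 4, (-w) % 4
        if ph or pw:
            a = np.pad(a, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        out = self.forward(a)
        return final_segmentation(out)[0][:h, :w]

    # -- persistence ----------------------------------------------------------
    def save(self, path):
        cfg = json.dumps(asdict(self.cfg)).encode()
        np.savez(path, __config__=np.frombuffer(cfg, dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "MultiScaleAttentionNet":
        with np.load(path) as z:
            cfg = NetworkConfig(**json.loads(bytes(z["__config__"].tobytes()).decode()))
            state = {k: z[k] for k in z.files if k != "__config__"}
        model = cls(cfg)
        model.load_state_dict(state)
        return model


# ---------------------------------------------------------------------------
# output decoding
# ---------------------------------------------------------------------------

def final_segmentation(h: HeadOutputs) -> np.ndarray:
    """Per-pixel label map from fused scores.

    Foreground class k scores p_cls_k * s_obj; background scores
    p_cls_0 * (1 - s_obj). Ties resolve to the lowest class id (numpy
    argmax takes the first maximum).
    """
    p = h.p_cls.data if isinstance(h.p_cls, Tensor) else np.asarray(h.p_cls)
    s = h.s_obj.data if isinstance(h.s_obj, Tensor) else np.asarray(h.s_obj)
    scores = p * s
    scores[:, 0] = p[:, 0] * (1.0 - s[:, 0])
    return scores.argmax(axis=1)


def _pairwise_iou(boxes: np.ndarray) -> np.ndarray:
    x0 = boxes[:, 0] - boxes[:, 2] / 2
    y0 = boxes[:, 1] - boxes[:, 3] / 2
    x1 = boxes[:, 0] + boxes[:, 2] / 2
    y1 = boxes[:, 1] + boxes[:, 3] / 2
    ix = np.maximum(0, np.minimum(x1[:, None], x1) - np.maximum(x0[:, None], x0))
    iy = np.maximum(0, np.minimum(y1[:, None], y1) - np.maximum(y0[:, None], y0))
    inter = ix * iy
    area = boxes[:, 2] * boxes[:, 3]
    union = area[:, None] + area - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def box_iou(a, b) -> float:
    return float(_pairwise_iou(np.stack([np.asarray(a, dtype=float),
                                         np.asarray(b, dtype=float)]))[0, 1])


def decode_boxes(h: HeadOutputs, threshold: float = 0.5, nms_iou: float = 0.5,
                 top_k: int = 200) -> list:
    """Anchor-free box decoding: one candidate per pixel with objectness
    above `threshold`, class from the foreground argmax at that pixel,
    greedy NMS at `nms_iou`. Returns dicts with the source pixel so the
    training loss can reach the box head tensor at that location.
    """
    p = h.p_cls.data
    s = h.s_obj.data[:, 0]
    b = h.b_map.data
    out = []
    for n in range(s.shape[0]):
        ys, xs = np.where(s[n] > threshold)
        if len(ys) == 0:
            continue
        scores = s[n, ys, xs]
        keep = np.argsort(scores)[::-1][:top_k]
        ys, xs, scores = ys[keep], xs[keep], scores[keep]
        # advanced-index result is (M, channels): pixels lead
        cls = p[n, 1:, ys, xs].argmax(axis=1) + 1 if p.shape[1] > 1 \
            else np.zeros(len(ys), dtype=int)
        boxes = b[n, :, ys, xs]  # (M,4)
        suppressed = np.zeros(len(ys), dtype=bool)
        iou = _pairwise_iou(boxes)
        for i in range(len(ys)):
            if suppressed[i]:
                continue
            out.append({
                "n": n, "y": int(ys[i]), "x": int(xs[i]),
                "class_id": int(cls[i]), "score": float(scores[i]),
                "box": boxes[i].astype(float),
            })
            suppressed |= (iou[i] > nms_iou) & (cls == cls[i])
            suppressed[i] = True
    return out
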