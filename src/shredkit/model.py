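"""Detection-network components: compressed residual/ELAN backbone, serial
spatial-pyramid pooling (SPPFCSPC), decoupled head, and the CIoU objective.

The architecture follows the improved single-stage detector layout this
package targets: a four-stage residual backbone whose Re-I-blocks fuse an
ELAN-style multi-branch concatenation path with a residual skip, compressed
to 1:2:2:1 blocks per stage; pyramid taps at strides 8/16/32 (stage 1
reaches P3 through a CBS unit and a downsampling max-pool, stage 2 through a
CBS unit, stage 3 feeds P4, and stage 4 feeds P5 through SPPFCSPC); and a
decoupled head that splits classification and localization branches after a
shared 1x1 channel reduction, with an objectness/IoU output on the
localization side.

Everything is exercised by construction, forward-pass shape checks,
parameter counting, loss evaluation, and a desk-scale smoke training run —
not full-scale training.  Anchors, strides and the loss recipe follow the
standard YOLO convention (3 anchors per level, strides 8/16/32, CIoU box
loss plus binary-cross-entropy objectness and classification terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ValidationError
from .nn import (
    CBS,
    Adam,
    Conv2d,
    Module,
    Sequential,
    Tensor,
    concat,
    maxpool2d,
    stack_scalars,
    upsample2x,
)
from .synthgen import Scene

# Standard YOLO anchor set (w, h in px) per level at strides 8 / 16 / 32.
DEFAULT_ANCHORS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)
STRIDES: tuple[int, ...] = (8, 16, 32)


# ---------------------------------------------------------------------------
# IoU / CIoU (scalar reference implementations of the loss geometry)
# ---------------------------------------------------------------------------


def _check_box(b: Sequence[float]) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = (float(v) for v in b)
    if not (x1 > x0 and y1 > y0):
        raise ValidationError(f"degenerate box {b}")
    return x0, y0, x1, y1


def iou(b: Sequence[float], bgt: Sequence[float]) -> float:
    """Intersection over union of two (x0, y0, x1, y1) boxes."""
    ax0, ay0, ax1, ay1 = _check_box(b)
    bx0, by0, bx1, by1 = _check_box(bgt)
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def ciou_loss(b: Sequence[float], bgt: Sequence[float]) -> float:
    """Complete-IoU loss: 1 − IoU + ρ²/c² + αv.

    ρ is the distance between box centers, c the diagonal of the smallest
    enclosing box, v = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))² the
    aspect-ratio consistency term, and α = v / (1 − IoU + v) its weight.
    """
    ax0, ay0, ax1, ay1 = _check_box(b)
    bx0, by0, bx1, by1 = _check_box(bgt)
    i = iou(b, bgt)
    rho2 = ((ax0 + ax1) / 2 - (bx0 + bx1) / 2) ** 2 + ((ay0 + ay1) / 2 - (by0 + by1) / 2) ** 2
    cw = max(ax1, bx1) - min(ax0, bx0)
    ch = max(ay1, by1) - min(ay0, by0)
    c2 = cw**2 + ch**2
    w, h = ax1 - ax0, ay1 - ay0
    wgt, hgt = bx1 - bx0, by1 - by0
    v = (4 / math.pi**2) * (math.atan(wgt / hgt) - math.atan(w / h)) ** 2
    alpha = 0.0 if v == 0 else v / (1 - i + v)
    return 1 - i + rho2 / c2 + alpha * v


def ciou_loss_t(b: Sequence[Tensor], bgt: Sequence[float]) -> Tensor:
    """Differentiable CIoU of a predicted box (four scalar Tensors) vs a fixed truth."""
    x0, y0, x1, y1 = b
    bx0, by0, bx1, by1 = _check_box(bgt)
    iw = x1.minimum(bx1) - x0.maximum(bx0)
    ih = y1.minimum(by1) - y0.maximum(by0)
    inter = iw.clamp_min(0.0) * ih.clamp_min(0.0)
    area_p = (x1 - x0) * (y1 - y0)
    union = area_p + (bx1 - bx0) * (by1 - by0) - inter
    i = inter / union
    rho2 = ((x0 + x1) * 0.5 - (bx0 + bx1) / 2) ** 2 + ((y0 + y1) * 0.5 - (by0 + by1) / 2) ** 2
    cw = x1.maximum(bx1) - x0.minimum(bx0)
    ch = y1.maximum(by1) - y0.minimum(by0)
    c2 = cw**2 + ch**2
    v = (
        ((x1 - x0) / (y1 - y0)).arctan() * (-1.0) + math.atan((bx1 - bx0) / (by1 - by0))
    ) ** 2 * (4 / math.pi**2)
    alpha = v / (1.0 - i + v + 1e-7)
    return 1.0 - i + rho2 / c2 + alpha * v


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneConfig:
    """Stage layout of the compressed residual backbone."""

    block_counts: tuple[int, int, int, int] = (1, 2, 2, 1)
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.block_counts) or any(c <= 0 for c in self.stage_channels):
            raise ValidationError("block counts and channels must be positive")


class ReIBlock(Module):
    """Multi-branch (ELAN-style) concatenation fused with a residual skip.

    A 1x1 reduction to C_out/2 feeds two stacked 3x3 convolutions whose taps
    are concatenated with the reduction and a 1x1 input projection, fused
    back to C_out by a 1x1 convolution, and added to an identity skip
    (projected when channel counts differ).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        mid = cout // 2
        self.reduce = CBS(cin, mid, 1, rng=rng)
        self.tap1 = CBS(mid, mid, 3, rng=rng)
        self.tap2 = CBS(mid, mid, 3, rng=rng)
        self.in_proj = CBS(cin, mid, 1, rng=rng)
        self.fuse = CBS(4 * mid, cout, 1, rng=rng)
        self.skip = None if cin == cout else Conv2d(cin, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        r = self.reduce(x)
        t1 = self.tap1(r)
        t2 = self.tap2(t1)
        fused = self.fuse(concat([self.in_proj(x), r, t1, t2], axis=1))
        identity = x if self.skip is None else self.skip(x)
        return (fused + identity).silu()


def build_re_i_block(cin: int, cout: int, seed: int = 0) -> ReIBlock:
    if cin <= 0 or cout <= 0:
        raise ValidationError("channel counts must be positive")
    return ReIBlock(cin, cout, np.random.default_rng(seed))


class Backbone(Module):
    """Four residual stages with pyramid taps.

    The stem downsamples x4; stages 2-4 each begin with a stride-2 CBS, so
    stage outputs sit at strides 4 / 8 / 16 / 32.  Taps: stage 1 → CBS + MP
    (stride 8) and stage 2 → CBS both feed P3; stage 3 → CBS feeds P4;
    stage 4 feeds the neck's SPPFCSPC which produces P5.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator, in_channels: int = 3):
        ch = cfg.stage_channels
        self.stem = Sequential(
            CBS(in_channels, ch[0] // 2, 3, stride=2, rng=rng),
            CBS(ch[0] // 2, ch[0], 3, stride=2, rng=rng),
        )
        self.stages: list[Sequential] = []
        cin = ch[0]
        for si, (n_blocks, cout) in enumerate(zip(cfg.block_counts, ch)):
            blocks: list[Module] = []
            if si > 0:
                blocks.append(CBS(cin, cout, 3, stride=2, rng=rng))
                cin = cout
            for _ in range(n_blocks):
                blocks.append(ReIBlock(cin, cout, rng))
                cin = cout
            self.stages.append(Sequential(*blocks))
        # taps toward the pyramid levels
        self.tap1_cbs = CBS(ch[0], ch[1] // 2, 1, rng=rng)  # stage1 → CBS → MP → P3
        self.tap2_cbs = CBS(ch[1], ch[1] // 2, 1, rng=rng)  # stage2 → CBS → P3
        self.tap3_cbs = CBS(ch[2], ch[2], 1, rng=rng)  # stage3 → CBS → P4
        self.cfg = cfg

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValidationError("input spatial size must be divisible by 32")
        s0 = self.stem(x)
        s1 = self.stages[0](s0)
        s2 = self.stages[1](s1)
        s3 = self.stages[2](s2)
        s4 = self.stages[3](s3)
        p3 = concat([maxpool2d(self.tap1_cbs(s1), 2, stride=2), self.tap2_cbs(s2)], axis=1)
        return {"p3": p3, "p4": self.tap3_cbs(s3), "stage4": s4}


def build_backbone(cfg: BackboneConfig | None = None, seed: int = 0) -> Backbone:
    return Backbone(cfg or BackboneConfig(), np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# SPPFCSPC neck block
# ---------------------------------------------------------------------------


class SPPFCSPC(Module):
    """Cross-stage-partial spatial pyramid pooling with a serial pool chain.

    Three serial 5x5 stride-1 max pools replace the parallel 5/9/13 pools of
    the SPPCSPC block: two chained 5x5 pools equal one 9x9 and three equal
    one 13x13, so the receptive field (and, pooling being parameter-free,
    the parameter count) is unchanged while each pool only pays for a 5x5
    window.  ``pool_mode`` can be switched to ``"parallel"`` on the same
    weights to verify the equivalence.
    """

    def __init__(self, channels: int, rng: np.random.Generator, pool_mode: str = "serial"):
        mid = max(channels // 2, 1)
        self.pre = Sequential(CBS(channels, mid, 1, rng=rng), CBS(mid, mid, 3, rng=rng), CBS(mid, mid, 1, rng=rng))
        self.shortcut = CBS(channels, mid, 1, rng=rng)
        self.post = Sequential(CBS(4 * mid, mid, 1, rng=rng), CBS(mid, mid, 3, rng=rng))
        self.out = CBS(2 * mid, channels, 1, rng=rng)
        self.pool_mode = pool_mode

    def forward(self, x: Tensor) -> Tensor:
        a = self.pre(x)
        if self.pool_mode == "serial":
            p1 = maxpool2d(a, 5)
            p2 = maxpool2d(p1, 5)
            p3 = maxpool2d(p2, 5)
        elif self.pool_mode == "parallel":
            p1 = maxpool2d(a, 5)
            p2 = maxpool2d(a, 9)
            p3 = maxpool2d(a, 13)
        else:
            raise ValidationError(f"unknown pool_mode {self.pool_mode!r}")
        a = self.post(concat([a, p1, p2, p3], axis=1))
        return self.out(concat([a, self.shortcut(x)], axis=1))


def build_sppfcspc(channels: int, seed: int = 0, pool_mode: str = "serial") -> SPPFCSPC:
    if channels <= 0:
        raise ValidationError("channels must be positive")
    return SPPFCSPC(channels, np.random.default_rng(seed), pool_mode=pool_mode)


# ---------------------------------------------------------------------------
# Decoupled head
# ---------------------------------------------------------------------------


class DecoupledHead(Module):
    """Per-level decoupled head: shared 1x1 reduction, then disjoint branches.

    The classification branch is convolutional; the localization branch —
    the per-location equivalent of a dense layer is a 1x1 convolution —
    produces 4 box channels plus an objectness/IoU channel per anchor.
    Output channel layout per anchor: (x, y, w, h, obj, classes...).
    """

    def __init__(self, cin: int, n_classes: int, n_anchors: int, rng: np.random.Generator, width: int = 64, zero_init: bool = False):
        if n_classes < 1:
            raise ValidationError("n_classes must be >= 1")
        self.n_classes = n_classes
        self.n_anchors = n_anchors
        self.reduce = CBS(cin, width, 1, rng=rng) if not zero_init else Conv2d(cin, width, 1, rng=rng, zero_init=True)
        self.cls_branch = CBS(width, width, 3, rng=rng)
        self.cls_out = Conv2d(width, n_anchors * n_classes, 1, rng=rng, zero_init=zero_init)
        self.reg_branch = CBS(width, width, 1, rng=rng)
        self.reg_out = Conv2d(width, n_anchors * 4, 1, rng=rng, zero_init=zero_init)
        self.obj_out = Conv2d(width, n_anchors * 1, 1, rng=rng, zero_init=zero_init)

    def forward(self, x: Tensor) -> Tensor:
        """Raw logits of shape (N, A*(5+C), H, W)."""
        shared = self.reduce(x)
        cls = self.cls_out(self.cls_branch(shared))
        reg_feat = self.reg_branch(shared)
        reg = self.reg_out(reg_feat)
        obj = self.obj_out(reg_feat)
        n, _, h, w = x.shape
        a, c = self.n_anchors, self.n_classes
        reg_r = reg.reshape(n, a, 4, h, w)
        obj_r = obj.reshape(n, a, 1, h, w)
        cls_r = cls.reshape(n, a, c, h, w)
        return concat([reg_r, obj_r, cls_r], axis=2).reshape(n, a * (5 + c), h, w)


def build_decoupled_head(
    channels_in: int, n_classes: int, n_anchors: int = 3, seed: int = 0, zero_init: bool = False
) -> DecoupledHead:
    return DecoupledHead(channels_in, n_classes, n_anchors, np.random.default_rng(seed), zero_init=zero_init)


# ---------------------------------------------------------------------------
# Full detector
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    n_classes: int = 4
    n_anchors: int = 3
    head_width: int = 64
    anchors: tuple = DEFAULT_ANCHORS


class DetectionModel(Module):
    """Backbone + SPPFCSPC + top-down fusion + per-level decoupled heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        ch = cfg.backbone.stage_channels
        self.cfg = cfg
        self.backbone = Backbone(cfg.backbone, rng)
        self.sppf = SPPFCSPC(ch[3], rng)
        self.p5_out = CBS(ch[3], ch[2], 1, rng=rng)
        self.p4_fuse = CBS(ch[2] + ch[2], ch[2], 1, rng=rng)
        self.p3_fuse = CBS(ch[1] + ch[2], ch[1], 1, rng=rng)
        self.heads = [
            DecoupledHead(ch[1], cfg.n_classes, cfg.n_anchors, rng, width=cfg.head_width),
            DecoupledHead(ch[2], cfg.n_classes, cfg.n_anchors, rng, width=cfg.head_width),
            DecoupledHead(ch[2], cfg.n_classes, cfg.n_anchors, rng, width=cfg.head_width),
        ]

    def forward(self, x: Tensor) -> list[Tensor]:
        taps = self.backbone(x)
        p5 = self.p5_out(self.sppf(taps["stage4"]))
        p4 = self.p4_fuse(concat([taps["p4"], upsample2x(p5)], axis=1))
        p3 = self.p3_fuse(concat([taps["p3"], upsample2x(p4)], axis=1))
        return [self.heads[0](p3), self.heads[1](p4), self.heads[2](p5)]


# ---------------------------------------------------------------------------
# Loss and smoke training
# ---------------------------------------------------------------------------


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    t = Tensor(targets.astype(np.float32))
    return (logits.softplus() - logits * t).mean()


def _assign(
    boxes_px: list[tuple[int, float, float, float, float]],
    shape: tuple[int, int],
    anchors=DEFAULT_ANCHORS,
) -> list[tuple[int, int, int, int, tuple[float, float, float, float], int]]:
    """Assign each truth box (class, x0, y0, x1, y1) to (level, anchor, gy, gx)."""
    out = []
    for cls, x0, y0, x1, y1 in boxes_px:
        w, h = x1 - x0, y1 - y0
        best = None
        for li, stride in enumerate(STRIDES):
            for ai, (aw, ah) in enumerate(anchors[li]):
                ratio = max(w / aw, aw / w) * max(h / ah, ah / h)
                if best is None or ratio < best[0]:
                    best = (ratio, li, ai)
        _, li, ai = best
        stride = STRIDES[li]
        gx = min(int((x0 + x1) / 2 / stride), shape[1] // stride - 1)
        gy = min(int((y0 + y1) / 2 / stride), shape[0] // stride - 1)
        out.append((li, ai, gy, gx, (x0, y0, x1, y1), cls))
    return out


def compute_loss(
    outputs: list[Tensor],
    truth_boxes_px: list[tuple[int, float, float, float, float]],
    image_shape: tuple[int, int],
    n_classes: int,
    anchors=DEFAULT_ANCHORS,
    weights: tuple[float, float, float] = (0.05, 1.0, 0.5),
) -> tuple[Tensor, dict[str, float]]:
    """CIoU box loss + BCE objectness + BCE classification for one image."""
    lw_box, lw_obj, lw_cls = weights
    assignments = _assign(truth_boxes_px, image_shape, anchors)
    box_terms: list[Tensor] = []
    cls_terms: list[Tensor] = []
    obj_terms: list[Tensor] = []
    for li, out in enumerate(outputs):
        n, ctot, h, w = out.shape
        a = ctot // (5 + n_classes)
        view = out.reshape(n, a, 5 + n_classes, h, w)
        obj_logits = view[:, :, 4, :, :]
        obj_target = np.zeros((n, a, h, w), dtype=np.float32)
        stride = STRIDES[li]
        for (lj, ai, gy, gx, truth, cls) in assignments:
            if lj != li:
                continue
            obj_target[0, ai, gy, gx] = 1.0
            tx = view[0, ai, 0, gy, gx]
            ty = view[0, ai, 1, gy, gx]
            tw = view[0, ai, 2, gy, gx]
            th = view[0, ai, 3, gy, gx]
            aw, ah = anchors[li][ai]
            cx = (tx.sigmoid() * 2.0 - 0.5 + gx) * stride
            cy = (ty.sigmoid() * 2.0 - 0.5 + gy) * stride
            # floor the decoded sizes: squared sigmoids underflow for very
            # negative logits and a zero side breaks the aspect-ratio term
            bw = ((tw.sigmoid() * 2.0) ** 2 * aw).clamp_min(1e-2)
            bh = ((th.sigmoid() * 2.0) ** 2 * ah).clamp_min(1e-2)
            pred = (cx - bw * 0.5, cy - bh * 0.5, cx + bw * 0.5, cy + bh * 0.5)
            box_terms.append(ciou_loss_t(pred, truth))
            cls_logits = stack_scalars([view[0, ai, 5 + c, gy, gx] for c in range(n_classes)])
            one_hot = np.zeros(n_classes, dtype=np.float32)
            one_hot[cls] = 1.0
            cls_terms.append(_bce_with_logits(cls_logits, one_hot))
        obj_terms.append(_bce_with_logits(obj_logits, obj_target))
    obj_loss = stack_scalars(obj_terms).mean()
    box_loss = stack_scalars(box_terms).mean() if box_terms else Tensor(0.0)
    cls_loss = stack_scalars(cls_terms).mean() if cls_terms else Tensor(0.0)
    total = box_loss * lw_box + obj_loss * lw_obj + cls_loss * lw_cls
    parts = {
        "box": float(box_loss.data),
        "obj": float(obj_loss.data),
        "cls": float(cls_loss.data),
        "total": float(total.data),
    }
    return total, parts


def _scene_input(scene: Scene) -> Tensor:
    img = scene.image.astype(np.float32) / 255.0
    return Tensor(img.transpose(2, 0, 1)[None])


def _scene_truths_px(scene: Scene) -> list[tuple[int, float, float, float, float]]:
    h, w = scene.shape
    return [(b.class_index, *b.to_xyxy(shape=(h, w))) for b in scene.boxes]


# Narrow desk-scale configuration used by the smoke run; the full-width
# default config is for construction and parameter accounting.
SMOKE_CONFIG = ModelConfig(
    backbone=BackboneConfig(stage_channels=(16, 32, 64, 128)), head_width=32
)


def make_smoke_scenes(n: int = 8, seed: int = 0, canvas: int = 256) -> list[Scene]:
    """Tiny scenes (2 ribbons, no block, no shadow) sized for smoke training."""
    from .synthgen import RibbonSpec, generate_scene

    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        labels = rng.choice(["Y", "G", "P", "Z"], size=2, replace=False)
        specs = []
        for lab in labels:
            length = float(rng.uniform(8.0, 16.0))
            specs.append(
                RibbonSpec(
                    class_label=str(lab),
                    length_mm=length,
                    width_mm=float(rng.uniform(1.0, 2.5)),
                    curvature=float(rng.uniform(-1.5, 1.5) / length),
                    ppmm=5.0,
                )
            )
        scenes.append(
            generate_scene(
                specs=specs,
                with_block=False,
                shadow_strength=0.0,
                seed=int(rng.integers(2**31)),
                canvas=(canvas, canvas),
                ppmm=5.0,
            )
        )
    return scenes


def smoke_train(
    scenes: list[Scene],
    epochs: int = 20,
    seed: int = 0,
    config: ModelConfig | None = None,
    lr: float = 1e-3,
) -> list[float]:
    """Train a small detector on a handful of tiny scenes; returns the per-epoch loss trace.

    Exercises the CIoU + objectness + classification objective end to end.
    Raises on fewer than 4 scenes or if the loss diverges.
    """
    if len(scenes) < 4:
        raise ValidationError("smoke training needs at least 4 scenes")
    model = DetectionModel(config or SMOKE_CONFIG, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    trace: list[float] = []
    for _ in range(epochs):
        epoch_loss = 0.0
        for scene in scenes:
            opt.zero_grad()
            outputs = model(_scene_input(scene))
            total, _ = compute_loss(outputs, _scene_truths_px(scene), scene.shape, model.cfg.n_classes)
            if not np.isfinite(total.data):
                raise FloatingPointError("smoke training diverged (non-finite loss)")
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
        trace.append(epoch_loss / len(scenes))
    return trace


# ---------------------------------------------------------------------------
# Inference helpers
# ---------------------------------------------------------------------------


def decode_predictions(
    outputs: list[Tensor],
    image_shape: tuple[int, int],
    n_classes: int,
    anchors=DEFAULT_ANCHORS,
    conf_threshold: float = 0.25,
    nms_iou: float = 0.45,
) -> list[tuple[int, float, float, float, float, float]]:
    """Decode raw head outputs to (class, x0, y0, x1, y1, confidence) boxes with NMS."""
    h_img, w_img = image_shape
    cands: list[tuple[float, int, float, float, float, float]] = []
    for li, out in enumerate(outputs):
        data = out.data
        n, ctot, h, w = data.shape
        a = ctot // (5 + n_classes)
        view = data.reshape(n, a, 5 + n_classes, h, w)
        stride = STRIDES[li]
        sig = 1.0 / (1.0 + np.exp(-view))
        for ai in range(a):
            aw, ah = anchors[li][ai]
            obj = sig[0, ai, 4]
            ys, xs = np.nonzero(obj >= conf_threshold)
            for gy, gx in zip(ys, xs):
                cls_probs = sig[0, ai, 5:, gy, gx]
                ci = int(np.argmax(cls_probs))
                conf = float(obj[gy, gx] * cls_probs[ci])
                if conf < conf_threshold:
                    continue
                cx = (sig[0, ai, 0, gy, gx] * 2 - 0.5 + gx) * stride
                cy = (sig[0, ai, 1, gy, gx] * 2 - 0.5 + gy) * stride
                bw = (sig[0, ai, 2, gy, gx] * 2) ** 2 * aw
                bh = (sig[0, ai, 3, gy, gx] * 2) ** 2 * ah
                cands.append((conf, ci, cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2))
    cands.sort(key=lambda t: -t[0])
    kept: list[tuple[int, float, float, float, float, float]] = []
    for conf, ci, x0, y0, x1, y1 in cands:
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(w_img)), min(y1, float(h_img))
        if x1 <= x0 or y1 <= y0:
            continue
        if any(k[0] == ci and iou((x0, y0, x1, y1), k[1:5]) > nms_iou for k in kept):
            continue
        kept.append((ci, x0, y0, x1, y1, conf))
    return kept


def count_parameters(module: Module) -> int:
    return module.count_parameters()


def save_weights(module: Module, path: str) -> None:
    """Serialize parameters in the numpy archive format."""
    np.savez(path, *[p.data for p in module.parameters()])


def load_weights(module: Module, path: str) -> None:
    with np.load(path) as archive:
        arrays = [archive[k] for k in archive.files]
    params = module.parameters()
    if len(arrays) != len(params):
        raise ValidationError("weight file does not match the model architecture")
    for p, arr in zip(params, arrays):
        if p.data.shape != arr.shape:
            raise ValidationError("weight shape mismatch")
        p.data = arr.astype(np.float32)
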