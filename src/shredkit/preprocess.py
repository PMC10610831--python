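"""Background-shadow elimination and dataset augmentation.

The shadow-elimination pipeline estimates the (possibly shadowed) background
of a light-ground image by grayscale dilation plus median filtering, takes
the absolute difference against the original grayscale (which cancels smooth
shadows and leaves the dark shreds as a bright foreground signal),
normalizes it to 0-255, and applies a local-mean adaptive threshold whose
window scales with the image, yielding a foreground mask used to enhance the
shreds and homogenize the background.

Augmentation implements the standard YOLO-style operators (hsv jitter,
translate, scale, horizontal flip, mosaic, mixup, paste-in) with boxes
transformed consistently with the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .io import DetectionBox, ValidationError
from .synthgen import Scene

# ---------------------------------------------------------------------------
# Shadow elimination, steps 1-5
# ---------------------------------------------------------------------------


def to_gray(image: np.ndarray) -> np.ndarray:
    """Luma grayscale conversion to uint8."""
    if image.ndim == 2:
        return np.asarray(image, dtype=np.uint8)
    g = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    return np.clip(np.round(g), 0, 255).astype(np.uint8)


def gray_dilate(image: np.ndarray, kernel_size: int = 3, iterations: int = 1) -> np.ndarray:
    """Step 1: grayscale conversion followed by morphological dilation.

    Dilation with a square structuring element takes the per-window maximum,
    so on a light background the bright ground expands and dark shreds
    shrink; with enough iterations thin dark objects vanish entirely,
    leaving a background estimate.
    """
    if image.size == 0:
        raise ValidationError("empty image")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValidationError("kernel_size must be odd and >= 1")
    g = to_gray(image)
    if kernel_size == 1 or iterations == 0:
        return g
    for _ in range(iterations):
        g = ndimage.maximum_filter(g, size=kernel_size, mode="nearest")
    return g


def median3(image: np.ndarray) -> np.ndarray:
    """Step 2: 3x3 median filter with replicate edge padding."""
    image = np.asarray(image)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValidationError("image must be at least 3x3")
    return ndimage.median_filter(image, size=3, mode="nearest")


def background_difference(original: np.ndarray, processed: np.ndarray) -> np.ndarray:
    """Step 3: per-pixel absolute difference; unchanged regions map to 0."""
    original = np.asarray(original)
    processed = np.asarray(processed)
    if original.shape != processed.shape:
        raise ValidationError("shape mismatch")
    return np.abs(original.astype(np.int16) - processed.astype(np.int16)).astype(np.uint8)


def normalize_0_255(image: np.ndarray) -> np.ndarray:
    """Step 4: min-max rescale to [0, 255]; a constant image maps to zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.round((image - lo) / (hi - lo) * 255).astype(np.uint8)


def default_window(shape: tuple[int, int]) -> int:
    """Adaptive-threshold window scaled to the image: max(15, min_dim/20), odd."""
    w = max(15, int(round(min(shape[:2]) / 20)))
    return w + 1 if w % 2 == 0 else w


def adaptive_enhance(
    image: np.ndarray,
    window: int | None = None,
    offset: float = 5.0,
    gain: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 5: local-mean adaptive threshold plus foreground enhancement.

    A pixel is foreground when it exceeds its local window mean by
    ``offset``.  The returned image is the input with foreground boosted by
    ``gain`` and non-foreground suppressed to zero; the boolean mask is
    returned alongside.
    """
    image = np.asarray(image)
    if window is None:
        window = default_window(image.shape)
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 3")
    local_mean = ndimage.uniform_filter(image.astype(float), size=window, mode="nearest")
    mask = image.astype(float) > local_mean + offset
    out = np.where(mask, np.clip(image.astype(float) * gain, 0, 255), 0.0)
    return np.round(out).astype(np.uint8), mask


@dataclass(frozen=True)
class ShadowParams:
    """Tunables of the composed shadow-elimination pipeline.

    ``dilate_iterations`` controls how far the 3x3 dilation erodes dark
    foreground when building the background estimate; the default erases
    shreds up to ~32 px wide (3 mm at 10 px/mm, the widest default shred).
    """

    kernel_size: int = 3
    dilate_iterations: int = 16
    window: int | None = None
    offset: float = 10.0
    gain: float = 1.2


@dataclass
class ShadowResult:
    image: np.ndarray  # homogenized RGB uint8
    foreground_mask: np.ndarray  # boolean
    difference: np.ndarray  # normalized difference image (uint8)


def eliminate_shadow(image: np.ndarray, params: ShadowParams | None = None) -> ShadowResult:
    """Steps 1-5 composed: homogenize the background, keep shred appearance.

    Foreground pixels keep their original color unchanged (``gain`` acts on
    the step-5 difference-image enhancement, not on the output colors, so a
    second pass over an already-clean image is a near no-op); the background
    is replaced by its median color, removing both the soft shadows and any
    low-frequency gradient.
    """
    params = params or ShadowParams()
    g0 = to_gray(image)
    bg = median3(gray_dilate(image, params.kernel_size, params.dilate_iterations))
    diff = background_difference(g0, bg)
    diff_n = normalize_0_255(diff)
    _, mask = adaptive_enhance(diff_n, params.window, params.offset, params.gain)
    # filtration: close pin-holes the local-mean threshold leaves inside wide
    # shreds and drop isolated speckle
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_opening(mask, structure=np.ones((2, 2), bool))
    rgb = image if image.ndim == 3 else np.stack([image] * 3, axis=-1)
    out = np.empty_like(rgb)
    if mask.any() and (~mask).any():
        bg_color = np.median(rgb[~mask].reshape(-1, 3), axis=0)
    else:
        bg_color = np.median(rgb.reshape(-1, 3), axis=0)
    out[:] = np.round(bg_color).astype(np.uint8)
    out[mask] = rgb[mask]
    return ShadowResult(image=out, foreground_mask=mask, difference=diff_n)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    """YOLO-style augmentation hyperparameters (fractional gains and probabilities)."""

    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.2
    scale: float = 0.5
    mosaic: float = 1.0
    mixup: float = 0.05
    paste_in: float = 0.05
    fliplr: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mosaic", "mixup", "paste_in", "fliplr"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1]")
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def is_identity(self) -> bool:
        return all(
            getattr(self, n) == 0
            for n in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale", "mosaic", "mixup", "paste_in", "fliplr")
        )


def _hsv_jitter(image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.hsv_h == 0 and cfg.hsv_s == 0 and cfg.hsv_v == 0:
        return image
    hsv = skcolor.rgb2hsv(image.astype(float) / 255.0)
    hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-cfg.hsv_h, cfg.hsv_h), 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-cfg.hsv_s, cfg.hsv_s)), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-cfg.hsv_v, cfg.hsv_v)), 0, 1)
    return np.clip(np.round(skcolor.hsv2rgb(hsv) * 255), 0, 255).astype(np.uint8)


def _affine(
    image: np.ndarray,
    boxes: list[DetectionBox],
    scale: float,
    tx_frac: float,
    ty_frac: float,
) -> tuple[np.ndarray, list[DetectionBox]]:
    """Scale about the image center, then translate; background fill."""
    h, w = image.shape[:2]
    out = np.empty_like(image)
    out[:] = np.median(image.reshape(-1, image.shape[-1]), axis=0).astype(np.uint8)
    zoomed = ndimage.zoom(image, (scale, scale, 1), order=1, mode="nearest")
    zh, zw = zoomed.shape[:2]
    # paste zoomed image so that its center lands at image center + translation
    cx = w / 2 + tx_frac * w
    cy = h / 2 + ty_frac * h
    x0 = int(round(cx - zw / 2))
    y0 = int(round(cy - zh / 2))
    sx0, sy0 = max(0, -x0), max(0, -y0)
    dx0, dy0 = max(0, x0), max(0, y0)
    cw = min(zw - sx0, w - dx0)
    ch = min(zh - sy0, h - dy0)
    if cw > 0 and ch > 0:
        out[dy0 : dy0 + ch, dx0 : dx0 + cw] = zoomed[sy0 : sy0 + ch, sx0 : sx0 + cw]
    new_boxes: list[DetectionBox] = []
    for b in boxes:
        bx0, by0, bx1, by1 = b.to_xyxy(shape=(h, w))
        nx0 = (bx0 - w / 2) * scale + cx
        nx1 = (bx1 - w / 2) * scale + cx
        ny0 = (by0 - h / 2) * scale + cy
        ny1 = (by1 - h / 2) * scale + cy
        nb = DetectionBox.from_xyxy(b.class_index, nx0, ny0, nx1, ny1, shape=(h, w), confidence=b.confidence)
        clipped = nb.clipped()
        if clipped is not None:
            new_boxes.append(clipped)
    return out, new_boxes


def _fliplr(image: np.ndarray, boxes: list[DetectionBox]) -> tuple[np.ndarray, list[DetectionBox]]:
    return image[:, ::-1].copy(), [replace(b, cx=1.0 - b.cx) for b in boxes]


def _mosaic(scenes: list[Scene], rng: np.random.Generator) -> Scene:
    """Stitch four scenes into a 2x2 grid at half resolution."""
    base = scenes[0]
    h, w = base.shape
    out = np.empty((h, w, 3), dtype=np.uint8)
    boxes: list[DetectionBox] = []
    quads = [(0, 0), (0, 1), (1, 0), (1, 1)]
    hh, hw = h // 2, w // 2
    for (qy, qx), sc in zip(quads, scenes[:4]):
        tile = ndimage.zoom(sc.image, (hh / sc.shape[0], hw / sc.shape[1], 1), order=1, mode="nearest")
        out[qy * hh : (qy + 1) * hh, qx * hw : (qx + 1) * hw] = tile[:hh, :hw]
        for b in sc.boxes:
            nb = DetectionBox(
                b.class_index,
                cx=b.cx / 2 + qx * 0.5,
                cy=b.cy / 2 + qy * 0.5,
                w=b.w / 2,
                h=b.h / 2,
                confidence=b.confidence,
            )
            clipped = nb.clipped()
            if clipped is not None:
                boxes.append(clipped)
    return Scene(image=out, boxes=boxes, truths=[], objects=[], ppmm=base.ppmm / 2)


def _mixup(a: Scene, b: Scene, rng: np.random.Generator) -> Scene:
    lam = float(rng.beta(8.0, 8.0))
    img_b = b.image
    if img_b.shape != a.image.shape:
        img_b = ndimage.zoom(
            img_b,
            (a.image.shape[0] / img_b.shape[0], a.image.shape[1] / img_b.shape[1], 1),
            order=1,
            mode="nearest",
        )
    blended = np.clip(
        np.round(a.image.astype(float) * lam + img_b.astype(float) * (1 - lam)), 0, 255
    ).astype(np.uint8)
    return Scene(image=blended, boxes=list(a.boxes) + list(b.boxes), truths=[], objects=[], ppmm=a.ppmm)


def _paste_in(scene: Scene, rng: np.random.Generator) -> Scene:
    """Copy one ribbon (by its mask) to a random free location in the same scene."""
    if not scene.objects:
        return scene
    obj = scene.objects[int(rng.integers(len(scene.objects)))]
    ys, xs = np.nonzero(obj.mask)
    oh, ow = ys.max() - ys.min() + 1, xs.max() - xs.min() + 1
    h, w = scene.shape
    if oh >= h or ow >= w:
        return scene
    ty = int(rng.integers(0, h - oh))
    tx = int(rng.integers(0, w - ow))
    image = scene.image.copy()
    local = obj.mask[ys.min() : ys.min() + oh, xs.min() : xs.min() + ow]
    patch = scene.image[ys.min() : ys.min() + oh, xs.min() : xs.min() + ow]
    region = image[ty : ty + oh, tx : tx + ow]
    region[local] = patch[local]
    new_box = DetectionBox.from_xyxy(
        obj.box.class_index, tx, ty, tx + ow, ty + oh, shape=(h, w)
    )
    return Scene(
        image=image,
        boxes=list(scene.boxes) + [new_box],
        truths=list(scene.truths),
        objects=list(scene.objects),
        block_px_length=scene.block_px_length,
        ppmm=scene.ppmm,
        shadow_strength=scene.shadow_strength,
    )


def augment(
    scene: Scene,
    cfg: AugmentConfig,
    seed: int = 0,
    pool: list[Scene] | None = None,
) -> Scene:
    """Apply the augmentation chain: hsv, translate/scale/flip, mosaic, mixup, paste-in.

    ``pool`` supplies the extra scenes drawn by mosaic and mixup; when absent
    those ops are skipped.  Boxes are transformed with the pixels, clipped to
    the frame, and dropped when fully outside.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    if cfg.is_identity:
        return scene
    image = _hsv_jitter(scene.image, cfg, rng)
    boxes = list(scene.boxes)
    if cfg.translate > 0 or cfg.scale > 0:
        s = 1.0 + (rng.uniform(-cfg.scale, cfg.scale) if cfg.scale > 0 else 0.0)
        tx = rng.uniform(-cfg.translate, cfg.translate) if cfg.translate > 0 else 0.0
        ty = rng.uniform(-cfg.translate, cfg.translate) if cfg.translate > 0 else 0.0
        image, boxes = _affine(image, boxes, s, tx, ty)
    if rng.uniform() < cfg.fliplr:
        image, boxes = _fliplr(image, boxes)
    out = Scene(
        image=image,
        boxes=boxes,
        truths=list(scene.truths),
        objects=list(scene.objects),
        block_px_length=scene.block_px_length,
        ppmm=scene.ppmm,
        shadow_strength=scene.shadow_strength,
    )
    if pool and len(pool) >= 3 and rng.uniform() < cfg.mosaic:
        others = [pool[int(j)] for j in rng.choice(len(pool), size=3, replace=False)]
        out = _mosaic([out, *others], rng)
    if pool and rng.uniform() < cfg.mixup:
        out = _mixup(out, pool[int(rng.integers(len(pool)))], rng)
    if rng.uniform() < cfg.paste_in:
        out = _paste_in(out, rng)
    return out
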