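"""Synthetic blended-shred scene generator with exact ground truth.

Real inspection-line images of blended tobacco shreds are not publicly
available, so every quantitative claim in this package is validated against
scenes produced here: curved constant-width ribbons of four classes
(Y tobacco silk, G cut stem, P expanded silk, Z reconstituted shred) on a
light background, with optional pairwise overlap, soft shadows, and a
rectangular calibration block of known millimetre size.  Each scene carries
its own YOLO annotations and per-object true centerline length and width,
which is what lets the measurement algorithm be scored without manual truth.

Geometry model: a ribbon is a constant-width tube swept along a circular arc
(curvature ``c``, radius ``1/|c|``) or a straight segment (``c = 0``), with
rounded end caps.  ``length_mm`` is the centerline (medial-axis) arc length;
the caps extend half a width beyond each end of the centerline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CLASS_INDEX, CLASS_NAMES, DetectionBox, ValidationError, write_image, write_yolo_labels

# Per-class base colors (RGB), chosen to be class-separable and darker than
# the background under the deepest allowed shadow (the shadow model darkens
# the background by at most ~25%, so every class luma stays >= 15 levels
# below the darkest background), not photorealistic.  Z is rendered without
# texture noise (uniform sheet); the others get additive speckle.
CLASS_COLORS: dict[str, tuple[int, int, int]] = {
    "Y": (150, 102, 40),   # yellow-brown silk
    "G": (176, 156, 114),  # pale stem
    "P": (188, 160, 126),  # light expanded silk
    "Z": (118, 92, 66),    # uniform reconstituted sheet
}
CLASS_TEXTURE_STD: dict[str, float] = {"Y": 12.0, "G": 9.0, "P": 7.0, "Z": 0.0}
BACKGROUND_COLOR: tuple[int, int, int] = (236, 233, 228)
BLOCK_COLOR: tuple[int, int, int] = (50, 52, 88)  # calibration block, dark blue-grey

# Calibration block physical size (mm): the standard rectangular reference
# block is 3 mm by 9 mm; its long side is the calibration length.
BLOCK_MM: tuple[float, float] = (3.0, 9.0)


class GeometryError(ValueError):
    """Ribbon or block does not fit the canvas."""


class PlacementError(RuntimeError):
    """Could not place all requested objects after bounded retries."""


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry and pose of one synthetic shred."""

    class_label: str
    length_mm: float
    width_mm: float
    curvature: float = 0.0  # signed, 1/mm; 0 = straight
    center: tuple[float, float] = (0.0, 0.0)  # (x, y) px on the canvas
    rotation_deg: float = 0.0
    ppmm: float = 10.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_INDEX:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if not self.length_mm > self.width_mm > 0:
            raise ValidationError("require length_mm > width_mm > 0")
        if self.ppmm <= 0:
            raise ValidationError("ppmm must be positive")

    @property
    def class_index(self) -> int:
        return CLASS_INDEX[self.class_label]


def centerline_points(spec: RibbonSpec, spacing_px: float = 0.25) -> np.ndarray:
    """Densely sampled centerline in canvas pixel coordinates, shape (N, 2) as (x, y).

    The curve is a circular arc of radius ``1/|curvature|`` (or a straight
    segment), centered on ``spec.center`` and rotated by ``rotation_deg``.
    """
    length_px = spec.length_mm * spec.ppmm
    n = max(int(math.ceil(length_px / spacing_px)) + 1, 2)
    s = np.linspace(-length_px / 2, length_px / 2, n)  # arc-length parameter
    c = spec.curvature / spec.ppmm  # 1/px
    if abs(c) < 1e-12:
        x, y = s, np.zeros_like(s)
    else:
        r = 1.0 / c
        # arc through the origin, tangent to the x axis at s = 0
        x = np.sin(s * c) * r
        y = (1.0 - np.cos(s * c)) * r
    th = math.radians(spec.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pts = np.stack([x, y], axis=1) @ rot.T
    pts[:, 0] += spec.center[0]
    pts[:, 1] += spec.center[1]
    return pts


def generate_ribbon(
    spec: RibbonSpec, shape: tuple[int, int], seed: int = 0
) -> tuple[np.ndarray, float, float]:
    """Render one ribbon as a boolean mask on an (H, W) canvas.

    Returns ``(mask, true_length_mm, true_width_mm)``.  The mask is the set
    of pixels within half a width of the centerline, so its medial axis has
    arc length ``length_mm * ppmm`` and its local thickness is
    ``width_mm * ppmm`` away from the rounded caps.  Deterministic: the
    geometry has no random component (``seed`` is accepted for interface
    symmetry with the scene generator).
    """
    h, w = shape
    pts = centerline_points(spec)
    r = spec.width_mm * spec.ppmm / 2.0
    if (
        pts[:, 0].min() - r < 0
        or pts[:, 1].min() - r < 0
        or pts[:, 0].max() + r > w - 1
        or pts[:, 1].max() + r > h - 1
    ):
        raise GeometryError("ribbon exceeds canvas")
    # Distance to the rasterized centerline via an exact EDT on a local patch.
    pad = int(math.ceil(r)) + 2
    x0 = int(math.floor(pts[:, 0].min())) - pad
    y0 = int(math.floor(pts[:, 1].min())) - pad
    x1 = int(math.ceil(pts[:, 0].max())) + pad + 1
    y1 = int(math.ceil(pts[:, 1].max())) + pad + 1
    patch = np.ones((y1 - y0, x1 - x0), dtype=bool)
    ix = np.clip(np.round(pts[:, 0]).astype(int) - x0, 0, x1 - x0 - 1)
    iy = np.clip(np.round(pts[:, 1]).astype(int) - y0, 0, y1 - y0 - 1)
    patch[iy, ix] = False
    dist = ndimage.distance_transform_edt(patch)
    local = dist <= r
    mask = np.zeros(shape, dtype=bool)
    mask[max(y0, 0) : y1, max(x0, 0) : x1] = local[max(y0, 0) - y0 :, max(x0, 0) - x0 :]
    return mask, spec.length_mm, spec.width_mm


@dataclass
class SceneObject:
    """One placed ribbon with its ground truth."""

    object_id: int
    spec: RibbonSpec
    mask: np.ndarray  # full-canvas boolean mask
    box: DetectionBox


@dataclass
class Scene:
    """An RGB image with exact annotations and per-object true sizes."""

    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[DetectionBox]
    truths: list[tuple[int, float, float]]  # (object id, length_mm, width_mm)
    objects: list[SceneObject] = field(default_factory=list)
    block_px_length: float | None = None
    block_rect: tuple[int, int, int, int] | None = None  # (y, x, height, width) px
    block_mm: tuple[float, float] = BLOCK_MM
    ppmm: float = 10.0
    shadow_strength: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def foreground_mask(self, include_block: bool = False) -> np.ndarray:
        """Union of all ribbon masks, optionally with the calibration block."""
        mask = np.zeros(self.shape, dtype=bool)
        for obj in self.objects:
            mask |= obj.mask
        if include_block and self.block_rect is not None:
            y, x, bh, bw = self.block_rect
            mask[y : y + bh, x : x + bw] = True
        return mask


def _mask_box(mask: np.ndarray, class_index: int) -> DetectionBox:
    ys, xs = np.nonzero(mask)
    h, w = mask.shape
    return DetectionBox.from_xyxy(
        class_index, xs.min(), ys.min(), xs.max() + 1, ys.max() + 1, shape=(h, w)
    )


def _apply_shadows(
    image: np.ndarray, objects: list[SceneObject], strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency multiplicative gradient plus a soft penumbra per ribbon.

    The penumbra hugs its ribbon (an overhead diffuse panel casts shadows
    offset by well under a millimetre) and is blurred at a ~1 mm scale, so
    shadow geometry is physical and independent of the canvas size.
    """
    h, w = image.shape[:2]
    ppmm = objects[0].spec.ppmm if objects else 10.0
    yy, xx = np.mgrid[0:h, 0:w]
    gx, gy = rng.uniform(-1, 1, 2)
    gradient = 1.0 - 0.3 * strength * ((gx * xx / w + gy * yy / h) + 1.0) / 2.0
    penumbra = np.zeros((h, w), dtype=float)
    for obj in objects:
        off = max(2, int(round(0.8 * ppmm * rng.uniform(0.5, 1.0))))
        shifted = np.roll(np.roll(obj.mask, off, axis=0), off, axis=1)
        penumbra = np.maximum(penumbra, shifted.astype(float))
    penumbra = ndimage.gaussian_filter(penumbra, sigma=1.0 * ppmm)
    fg = np.zeros((h, w), dtype=bool)
    for obj in objects:
        fg |= obj.mask
    factor = gradient * (1.0 - strength * 0.5 * penumbra)
    factor = np.where(fg, 1.0, factor)  # shreds themselves are not shadowed
    out = image.astype(float) * factor[..., None]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _paint_ribbon(image: np.ndarray, obj: SceneObject, rng: np.random.Generator) -> None:
    color = np.array(CLASS_COLORS[obj.spec.class_label], dtype=float)
    n = int(obj.mask.sum())
    std = CLASS_TEXTURE_STD[obj.spec.class_label]
    noise = rng.normal(0.0, std, size=(n, 3)) if std > 0 else 0.0
    image[obj.mask] = np.clip(np.round(color[None, :] + noise), 0, 255).astype(np.uint8)


def _default_spec(
    label: str, shape: tuple[int, int], ppmm: float, rng: np.random.Generator
) -> RibbonSpec:
    """Draw a realistic shred geometry: 8-30 mm long, 1-3 mm wide, arc bend up to ~150 deg."""
    length = float(rng.uniform(8.0, 30.0))
    width = float(rng.uniform(1.0, min(3.0, length / 4)))
    max_curv = math.radians(150.0) / length  # total turn <= 150 degrees
    curvature = float(rng.uniform(-max_curv, max_curv))
    return RibbonSpec(
        class_label=label,
        length_mm=length,
        width_mm=width,
        curvature=curvature,
        center=(0.0, 0.0),
        rotation_deg=float(rng.uniform(0.0, 360.0)),
        ppmm=ppmm,
    )


def _place_block(
    image: np.ndarray, ppmm: float, rng: np.random.Generator, occupied: np.ndarray
) -> tuple[float, tuple[int, int, int, int]]:
    h, w = image.shape[:2]
    bw = int(round(BLOCK_MM[0] * ppmm))  # short side
    bl = int(round(BLOCK_MM[1] * ppmm))  # long side, the calibration length
    for _ in range(200):
        y = int(rng.integers(2, h - bw - 2))
        x = int(rng.integers(2, w - bl - 2))
        region = occupied[y : y + bw, x : x + bl]
        if not region.any():
            image[y : y + bw, x : x + bl] = BLOCK_COLOR
            occupied[y : y + bw, x : x + bl] = True
            return float(bl), (y, x, bw, bl)
    raise PlacementError("no room for the calibration block")


def generate_scene(
    n_per_class: dict[str, int] | None = None,
    overlap_fraction: float = 0.0,
    with_block: bool = True,
    shadow_strength: float = 0.3,
    seed: int = 0,
    canvas: tuple[int, int] = (1280, 1280),
    ppmm: float = 10.0,
    specs: list[RibbonSpec] | None = None,
    max_retries: int = 200,
) -> Scene:
    """Render a blended-shred scene with exact annotations.

    ``overlap_fraction`` is the fraction of ribbons deliberately placed to
    overlap a previously placed ribbon (the rest are placed disjoint),
    emulating the multi-labeled overlapped shreds of real blended images.
    When ``specs`` is given, their poses are re-drawn at placement time and
    ``n_per_class`` is ignored.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValidationError("overlap_fraction must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    h, w = canvas
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = BACKGROUND_COLOR

    if specs is None:
        if n_per_class is None:
            n_per_class = {c: 1 for c in CLASS_NAMES}
        specs = []
        for label in CLASS_NAMES:
            for _ in range(n_per_class.get(label, 0)):
                specs.append(_default_spec(label, canvas, ppmm, rng))

    n_total = len(specs)
    want_overlap = np.zeros(n_total, dtype=bool)
    if n_total > 1 and overlap_fraction > 0:
        k = int(round(overlap_fraction * n_total))
        want_overlap[rng.choice(n_total - 1, size=min(k, n_total - 1), replace=False) + 1] = True

    objects: list[SceneObject] = []
    occupied = np.zeros((h, w), dtype=bool)
    for i, spec in enumerate(specs):
        placed = False
        half_extent = (spec.length_mm + spec.width_mm) * spec.ppmm / 2 + 4
        if 2 * half_extent >= min(h, w):
            raise GeometryError(f"ribbon {i} cannot fit the canvas at any pose")
        for _ in range(max_retries):
            if want_overlap[i] and objects:
                anchor = objects[int(rng.integers(len(objects)))]
                ax, ay = anchor.spec.center
                jitter = anchor.spec.length_mm * anchor.spec.ppmm * 0.2
                cx = float(np.clip(ax + rng.uniform(-jitter, jitter), half_extent, w - half_extent))
                cy = float(np.clip(ay + rng.uniform(-jitter, jitter), half_extent, h - half_extent))
            else:
                cx = float(rng.uniform(half_extent, w - half_extent))
                cy = float(rng.uniform(half_extent, h - half_extent))
            posed = RibbonSpec(
                class_label=spec.class_label,
                length_mm=spec.length_mm,
                width_mm=spec.width_mm,
                curvature=spec.curvature,
                center=(cx, cy),
                rotation_deg=float(rng.uniform(0.0, 360.0)),
                ppmm=spec.ppmm,
            )
            try:
                mask, tl, tw = generate_ribbon(posed, (h, w))
            except GeometryError:
                continue
            overlaps = bool((mask & occupied).any())
            if overlaps != bool(want_overlap[i] and objects):
                continue
            obj = SceneObject(
                object_id=i,
                spec=posed,
                mask=mask,
                box=_mask_box(mask, posed.class_index),
            )
            objects.append(obj)
            occupied |= mask
            placed = True
            break
        if not placed:
            raise PlacementError(f"could not place ribbon {i} after {max_retries} retries")

    for obj in objects:
        _paint_ribbon(image, obj, rng)

    block_px = None
    block_rect = None
    if with_block:
        block_px, block_rect = _place_block(image, ppmm, rng, occupied)

    if shadow_strength > 0:
        image = _apply_shadows(image, objects, shadow_strength, rng)

    return Scene(
        image=image,
        boxes=[o.box for o in objects],
        truths=[(o.object_id, o.spec.length_mm, o.spec.width_mm) for o in objects],
        objects=objects,
        block_px_length=block_px,
        block_rect=block_rect,
        ppmm=ppmm,
        shadow_strength=shadow_strength,
    )


def build_manifest(
    counts_by_label: dict[str, int],
    ratio: tuple[int, int] = (7, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign record ids to train/test splits, per label, at an exact ratio.

    The test count per label is ``floor(n * test / (train + test))`` and the
    remainder goes to train, so ratios that divide the counts are honored
    exactly (e.g. 1000 records at 7:3 give 700 train / 300 test).  Assignment
    within a label is a seeded shuffle.
    """
    tr, te = ratio
    if tr < 0 or te < 0 or tr + te <= 0:
        raise ValidationError("ratio parts must be non-negative with a positive sum")
    rng = np.random.Generator(np.random.PCG64(seed))
    rows: list[tuple[str, str, str]] = []
    for label in sorted(counts_by_label):
        n = counts_by_label[label]
        if n <= 0 or n != int(n):
            raise ValidationError(f"count for {label!r} must be a positive integer")
        n_test = (n * te) // (tr + te)
        ids = [f"{label}_{i:06d}" for i in range(n)]
        order = rng.permutation(n)
        test_ids = {ids[j] for j in order[:n_test]}
        rows.extend(
            (rid, label, "test" if rid in test_ids else "train") for rid in ids
        )
    return pd.DataFrame(rows, columns=["record_id", "label", "split"])


def save_scene(scene: Scene, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Write the PNG image, YOLO labels, and ground-truth CSV for one scene."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}.png",
        "labels": outdir / f"{stem}.txt",
        "truths": outdir / f"{stem}_truth.csv",
    }
    write_image(paths["image"], scene.image)
    write_yolo_labels(paths["labels"], scene.boxes)
    truth_df = pd.DataFrame(
        [
            (oid, CLASS_NAMES[scene.objects[k].spec.class_index], length, width)
            for k, (oid, length, width) in enumerate(scene.truths)
        ],
        columns=["object_id", "class", "length_mm", "width_mm"],
    )
    truth_df["block_px_length"] = scene.block_px_length
    truth_df["block_mm_length"] = scene.block_mm[1]
    truth_df["ppmm"] = scene.ppmm
    truth_df.to_csv(paths["truths"], index=False)
    return paths
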