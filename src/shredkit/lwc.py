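"""Two-dimensional size calculation for curved shreds (the LWC algorithm).

Each detected object is cropped by its box, binarized, and reduced to the
contour whose centroid lies nearest the box center (removing fragments of
neighboring shreds that intrude into the crop).  The mask is rotated so its
minimum-area bounding rectangle is horizontal, then cut into ``n`` vertical
strips of width x1/n:

* **Length** — the foreground centroid of every non-empty strip is computed,
  a cubic smoothing spline is fitted through the ordered centroids, and the
  centerline arc length is integrated by dense chordal sampling.  The fitted
  centerline is extended to the mask's horizontal extent minus half the
  measured width at each end, so rounded end caps contribute their physical
  extent without being double counted.
* **Width** — in every strip the maximum inscribed circle of the object is
  found via the interior Euclidean distance transform (the strip's maximum
  distance value is the radius); the object width is the mean diameter over
  strips.

Pixel measurements convert to millimetres through a calibration factor
``pixels_per_mm = block_pixel_length / block_mm_length`` obtained from a
rectangular reference block of known size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Polygon

from skimage.filters import threshold_otsu
from skimage.graph import MCP_Geometric
from skimage.measure import label as sk_label

from .io import CLASS_NAMES, DetectionBox, ValidationError
from .preprocess import to_gray

__all__ = [
    "Calibration",
    "RotatedCrop",
    "CenterlineFit",
    "WidthProfile",
    "SizeMeasurement",
    "calibrate",
    "detect_block_px",
    "crop_and_select",
    "rotate_to_horizontal",
    "slice_strips",
    "length_of",
    "width_of",
    "measure_scene",
    "aggregate_report",
]


class EmptyObjectError(ValueError):
    """No usable contour found inside a detection crop."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale from the reference block."""

    pixels_per_mm: float
    block_pixel_length: float | None = None
    block_mm_length: float | None = None

    def to_mm(self, px: float) -> float:
        return px / self.pixels_per_mm


def calibrate(block_pixel_length: float, block_mm_length: float) -> Calibration:
    if block_pixel_length <= 0 or block_mm_length <= 0:
        raise ValidationError("block lengths must be positive")
    return Calibration(
        pixels_per_mm=block_pixel_length / block_mm_length,
        block_pixel_length=block_pixel_length,
        block_mm_length=block_mm_length,
    )


def _min_area_rect(mask: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area bounding rectangle of a boolean mask.

    Returns ``(long_side, short_side, angle_deg)`` where ``angle_deg`` is the
    rotation that makes the long side horizontal.  Pixel extents are measured
    between pixel-center hulls plus one pixel of support.
    """
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValidationError("empty mask")
    pts = np.stack([xs, ys], axis=1).astype(float)
    if len(pts) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        # degenerate: a line or a point
        long_side = float(max(np.ptp(xs), np.ptp(ys)) + 1)
        short_side = float(min(np.ptp(xs), np.ptp(ys)) + 1)
        if short_side == long_side == 1.0:
            raise ValidationError("degenerate single-pixel mask")
        angle = 0.0 if np.ptp(xs) >= np.ptp(ys) else 90.0
        return long_side, short_side, angle
    hull = ConvexHull(pts)
    poly = Polygon(pts[hull.vertices]).minimum_rotated_rectangle
    coords = np.asarray(poly.exterior.coords)[:4]
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    if l1 >= l2:
        long_side, short_side, vec = l1, l2, e1
    else:
        long_side, short_side, vec = l2, l1, e2
    angle = math.degrees(math.atan2(vec[1], vec[0]))
    # rotation that maps the long edge onto the +x axis
    return float(long_side + 1), float(short_side + 1), -angle


@dataclass
class RotatedCrop:
    """Object mask rotated so its minimum-area rectangle is horizontal.

    ``x1`` is the rectangle's long (horizontal) side and ``y1`` the short
    side, in pixels; the coordinate frame follows the rotated mask array
    (origin effectively anchored at the rectangle corner).
    """

    mask: np.ndarray
    x1: float
    y1: float
    angle_deg: float  # rotation applied to the input mask

    def distance_transform(self) -> np.ndarray:
        # pad so the crop edge counts as boundary (the mask is cropped tight)
        padded = np.pad(self.mask, 1)
        return ndimage.distance_transform_edt(padded)[1:-1, 1:-1]


def rotate_to_horizontal(mask: np.ndarray) -> RotatedCrop:
    """Rotate the mask so that its minimum-area rectangle lies horizontal."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() <= 1:
        raise ValidationError("mask must contain more than one pixel")
    long_side, short_side, angle = _min_area_rect(mask)
    norm = ((angle + 90) % 180) - 90  # rotate by the smaller equivalent angle
    rotated = ndimage.rotate(mask.astype(float), -norm, order=1, reshape=True) >= 0.5
    ys, xs = np.nonzero(rotated)
    rotated = rotated[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    # raster rotation can leave a residual; refresh extents from the result
    x1 = float(rotated.shape[1])
    y1 = float(rotated.shape[0])
    if y1 > x1:  # guard: keep the long side horizontal
        rotated = rotated.T.copy()
        x1, y1 = y1, x1
    return RotatedCrop(mask=rotated, x1=x1, y1=y1, angle_deg=-norm)


def crop_and_select(
    image: np.ndarray, box: DetectionBox, invert: bool | None = None
) -> np.ndarray:
    """Binarize a detection crop and keep the contour nearest the box center.

    Otsu thresholding on the grayscale crop; by default the darker phase is
    foreground (shreds on a light ground), switchable with ``invert``.
    Among connected components, the one whose centroid is nearest the box
    center wins; exact ties go to the larger area.
    """
    h, w = image.shape[:2]
    x0, y0, x1, y1 = box.to_xyxy(shape=(h, w))
    ix0, iy0 = max(int(math.floor(x0)), 0), max(int(math.floor(y0)), 0)
    ix1, iy1 = min(int(math.ceil(x1)), w), min(int(math.ceil(y1)), h)
    if ix1 <= ix0 or iy1 <= iy0:
        raise ValidationError("box lies outside the image")
    crop = to_gray(image[iy0:iy1, ix0:ix1])
    if crop.min() == crop.max():
        raise EmptyObjectError("uniform crop: no contour found")
    t = threshold_otsu(crop)
    dark = crop <= t
    if invert is None:
        invert = False
    binary = ~dark if invert else dark
    labels, n = sk_label(binary, return_num=True, connectivity=2)
    if n == 0:
        raise EmptyObjectError("no contour found in crop")
    center = np.array([(iy1 - iy0) / 2, (ix1 - ix0) / 2])
    best = None
    for lab in range(1, n + 1):
        component = labels == lab
        area = int(component.sum())
        if area < 4:
            continue
        centroid = np.array(ndimage.center_of_mass(component))
        d = float(np.hypot(*(centroid - center)))
        key = (round(d, 6), -area)
        if best is None or key < best[0]:
            best = (key, component)
    if best is None:
        raise EmptyObjectError("no contour of usable size found in crop")
    return best[1]


def slice_strips(rc: RotatedCrop, n: int) -> list[np.ndarray]:
    """Cut the rotated mask into n vertical strips of width x1/n.

    Returns full-height boolean sub-masks partitioning the columns; strips
    narrower than 2 px are rejected.
    """
    if n < 2:
        raise ValidationError("need at least 2 strips")
    dx = rc.x1 / n
    if dx < 2.0:
        raise ValidationError(f"strip width {dx:.2f} px < 2 px; reduce n")
    edges = np.round(np.linspace(0, rc.x1, n + 1)).astype(int)
    return [rc.mask[:, edges[i] : edges[i + 1]] for i in range(n)]


@dataclass
class CenterlineFit:
    """Strip centroids, fitted curve samples, and the centerline arc length."""

    strip_count: int
    dx: float
    centroids: np.ndarray  # (m, 2) as (x, y) px
    curve: np.ndarray  # dense (x, y) samples of the fitted centerline
    arc_length_px: float

    @property
    def chord_px(self) -> float:
        return float(np.hypot(*(self.centroids[-1] - self.centroids[0])))


@dataclass
class WidthProfile:
    diameters_px: np.ndarray  # per non-empty strip
    mean_diameter_px: float


def _strip_centroids(rc: RotatedCrop, n: int) -> tuple[np.ndarray, float]:
    dx = rc.x1 / n
    edges = np.round(np.linspace(0, rc.x1, n + 1)).astype(int)
    pts = []
    for i in range(n):
        strip = rc.mask[:, edges[i] : edges[i + 1]]
        if not strip.any():
            continue
        ys, xs = np.nonzero(strip)
        pts.append((edges[i] + xs.mean(), ys.mean()))
    return np.asarray(pts, dtype=float), dx

def _width_profile(rc: RotatedCrop, n: int) -> WidthProfile:
    dist = rc.distance_transform()
    edges = np.round(np.linspace(0, rc.x1, n + 1)).astype(int)
    diams = []
    for i in range(n):
        strip = dist[:, edges[i] : edges[i + 1]]
        if strip.size == 0 or not strip.any():
            continue
        r = float(strip.max())
        diams.append(2.0 * r - 1.0)  # pixel-center EDT to continuous diameter
    diams = np.asarray(diams, dtype=float)
    return WidthProfile(diameters_px=diams, mean_diameter_px=float(diams.mean()))


def _fit_centerline(centroids: np.ndarray, samples: int = 1000) -> np.ndarray:
    """Smooth parametric curve through strip centroids ordered by x.

    A chord-length-parametrized cubic smoothing spline (when at least 4
    centroids exist; a polyline otherwise), so near-vertical centerline
    sections of strongly bent shreds are representable.  Returns dense
    (x, y) samples spanning the centroid range.
    """
    pts = centroids[np.argsort(centroids[:, 0])]
    if len(pts) >= 4:
        chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
        u = chord / chord[-1]
        tck, _ = splprep([pts[:, 0], pts[:, 1]], u=u, k=3, s=0.5 * len(pts))
        xs, ys = splev(np.linspace(0, 1, samples), tck)
        return np.stack([xs, ys], axis=1)
    t = np.linspace(0, 1, samples)
    seg = np.linspace(0, len(pts) - 1, samples)
    return np.stack(
        [np.interp(seg, np.arange(len(pts)), pts[:, 0]), np.interp(seg, np.arange(len(pts)), pts[:, 1])],
        axis=1,
    )


def _end_extensions(mask: np.ndarray, curve: np.ndarray) -> tuple[float, float]:
    """Residual path length beyond each end of the fitted centerline.

    Every mask pixel is assigned to its nearest curve sample; the pixels
    owned by an end sample form that end's residual region (the strip
    remainder and the cap, including a steeply bent limb the vertical strips
    could not resolve).  The extension is the largest within-mask geodesic
    distance from the curve end to a residual pixel lying in the forward
    cone (±60°) of the outward end tangent, so it measures the path to the
    true tip whatever direction the shred bends while ignoring laterally
    offset boundary pixels that only reflect the object's width.
    """
    ys, xs = np.nonzero(mask)
    pix = np.stack([xs, ys], axis=1).astype(float)
    owner = cKDTree(curve).query(pix, k=1)[1]
    costs = np.where(mask, 1.0, np.inf)
    exts = []
    for end_pt, end_idx, tangent in (
        (curve[0], 0, curve[0] - curve[1]),
        (curve[-1], len(curve) - 1, curve[-1] - curve[-2]),
    ):
        tnorm = float(np.hypot(*tangent))
        region = owner == end_idx
        if not region.any() or tnorm == 0:
            exts.append(0.0)
            continue
        rel = pix[region] - end_pt
        rnorm = np.hypot(rel[:, 0], rel[:, 1])
        with np.errstate(invalid="ignore"):
            forward = (rel @ (tangent / tnorm)) / np.where(rnorm > 0, rnorm, 1.0) >= 0.5
        if not forward.any():
            exts.append(0.0)
            continue
        # geodesic distances from the mask pixel nearest the curve end
        k = int(np.argmin(((pix - end_pt) ** 2).sum(axis=1)))
        mcp = MCP_Geometric(costs)
        dist_map, _ = mcp.find_costs([(int(pix[k, 1]), int(pix[k, 0]))])
        region_dists = dist_map[ys[region][forward], xs[region][forward]]
        region_dists = region_dists[np.isfinite(region_dists)]
        exts.append(float(region_dists.max()) if len(region_dists) else 0.0)
    return exts[0], exts[1]


def length_of(rc: RotatedCrop, n: int, cal: Calibration) -> tuple[float, CenterlineFit]:
    """Centerline length of the rotated object in millimetres.

    Arc length of the fitted centerline between the end centroids, extended
    along the end tangents to the mask tips, minus half the measured width
    at each end: the rounded caps extend half a width beyond the ends of the
    medial axis, so the tip-to-tip path overstates the centerline by exactly
    one width.
    """
    centroids, dx = _strip_centroids(rc, n)
    if len(centroids) < 2:
        raise ValidationError("need at least 2 non-empty strips")
    wp = _width_profile(rc, n)
    half_w = max(wp.mean_diameter_px / 2.0, 0.0)
    curve = _fit_centerline(centroids)
    seg = np.diff(curve, axis=0)
    arc = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    ext0, ext1 = _end_extensions(rc.mask, curve)
    arc += ext0 + ext1
    arc = max(arc, float(np.hypot(*(centroids[-1] - centroids[0]))))  # >= chord
    fit = CenterlineFit(
        strip_count=n, dx=dx, centroids=centroids, curve=curve, arc_length_px=arc
    )
    length_px = max(arc - 2 * half_w, 1.0)
    return cal.to_mm(length_px), fit


def width_of(rc: RotatedCrop, n: int, cal: Calibration) -> tuple[float, WidthProfile]:
    """Mean maximum-inscribed-circle diameter of the object in millimetres."""
    centroids, _ = _strip_centroids(rc, n)
    if len(centroids) < 2:
        raise ValidationError("need at least 2 non-empty strips")
    wp = _width_profile(rc, n)
    return cal.to_mm(wp.mean_diameter_px), wp


@dataclass
class SizeMeasurement:
    object_id: int
    class_name: str
    length_mm: float
    width_mm: float
    rel_err_len_pct: float | None = None
    rel_err_wid_pct: float | None = None
    error: str | None = None


def detect_block_px(image: np.ndarray, color_tol: float = 40.0) -> float:
    """Locate the calibration block by color and return its long side in px."""
    from .synthgen import BLOCK_COLOR

    diff = np.abs(image.astype(float) - np.array(BLOCK_COLOR, dtype=float)).sum(axis=-1)
    mask = diff < color_tol
    if not mask.any():
        raise EmptyObjectError("calibration block not found")
    labels, n = sk_label(mask, return_num=True)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    block = labels == (1 + int(np.argmax(sizes)))
    long_side, _, _ = _min_area_rect(block)
    return float(long_side)


def measure_scene(
    image: np.ndarray,
    boxes: list[DetectionBox],
    cal: Calibration,
    n: int = 50,
    truths: dict[int, tuple[float, float]] | None = None,
    invert: bool | None = None,
) -> pd.DataFrame:
    """Measure every detected object; failures are recorded, not raised.

    ``truths`` maps object index to (true length mm, true width mm); when
    given, signed relative errors ``100 * (measured - actual) / actual`` are
    reported per object.
    """
    rows: list[SizeMeasurement] = []
    for i, box in enumerate(boxes):
        try:
            mask = crop_and_select(image, box, invert=invert)
            rc = rotate_to_horizontal(mask)
            strips = max(2, min(n, int(rc.x1 // 2)))
            length_mm, _ = length_of(rc, strips, cal)
            width_mm, _ = width_of(rc, strips, cal)
            m = SizeMeasurement(i, CLASS_NAMES[box.class_index], length_mm, width_mm)
            if truths and i in truths:
                tl, tw = truths[i]
                m.rel_err_len_pct = 100.0 * (length_mm - tl) / tl
                m.rel_err_wid_pct = 100.0 * (width_mm - tw) / tw
            rows.append(m)
        except (ValidationError, EmptyObjectError) as exc:
            rows.append(
                SizeMeasurement(i, CLASS_NAMES[box.class_index], float("nan"), float("nan"), error=str(exc))
            )
    return pd.DataFrame([vars(r) for r in rows])


def aggregate_report(
    measurements: pd.DataFrame, truths: dict[int, tuple[float, float]]
) -> pd.DataFrame:
    """Per-class and overall aggregate errors on summed sizes.

    The aggregate signed relative error compares the sum of measured sizes
    with the sum of true sizes within each class (rows ``Total-Y`` ...
    ``Total-Z``) and over all objects (row ``Total``).
    """
    ok = measurements[measurements["error"].isna()].copy()
    ok["true_len"] = ok["object_id"].map(lambda i: truths[i][0])
    ok["true_wid"] = ok["object_id"].map(lambda i: truths[i][1])
    rows = []

    def _agg(name: str, sub: pd.DataFrame) -> None:
        if len(sub) == 0:
            return
        el = 100.0 * (sub["length_mm"].sum() - sub["true_len"].sum()) / sub["true_len"].sum()
        ew = 100.0 * (sub["width_mm"].sum() - sub["true_wid"].sum()) / sub["true_wid"].sum()
        rows.append((name, len(sub), round(el, 2), round(ew, 2)))

    for cname in CLASS_NAMES:
        _agg(f"Total-{cname}", ok[ok["class_name"] == cname])
    _agg("Total", ok)
    return pd.DataFrame(rows, columns=["sample", "n_objects", "rel_err_len_pct", "rel_err_wid_pct"])
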