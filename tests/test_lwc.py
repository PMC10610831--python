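"""Size-calculation algorithm: calibration, rotation, strips, length/width accuracy."""

import math

import numpy as np
import pytest
from scipy import ndimage

from shredkit import lwc
from shredkit import synthgen as sg
from shredkit.io import DetectionBox, ValidationError

from conftest import render_ribbon


def measure_mask(mask, cal, n_max=50):
    rc = lwc.rotate_to_horizontal(mask)
    n = max(2, min(n_max, int(rc.x1 // 2)))
    length, fit = lwc.length_of(rc, n, cal)
    width, wp = lwc.width_of(rc, n, cal)
    return length, width, fit, wp


class TestCalibrate:
    def test_division(self):
        assert lwc.calibrate(90, 9).pixels_per_mm == pytest.approx(10.0)
        assert lwc.calibrate(90, 3).pixels_per_mm == pytest.approx(30.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            lwc.calibrate(0, 9)
        with pytest.raises(ValidationError):
            lwc.calibrate(90, -1)

    def test_end_to_end_on_rendered_block(self):
        sc = sg.generate_scene(n_per_class={"Y": 1}, with_block=True, seed=8, canvas=(640, 640), ppmm=10)
        measured_px = lwc.detect_block_px(sc.image)
        cal = lwc.calibrate(measured_px, 9.0)
        assert cal.pixels_per_mm == pytest.approx(10.0, rel=0.02)


class TestCropAndSelect:
    def test_single_ribbon_recovered(self, shadow_free_scene):
        obj = shadow_free_scene.objects[0]
        mask = lwc.crop_and_select(shadow_free_scene.image, obj.box)
        x0, y0, x1, y1 = obj.box.to_xyxy(shape=shadow_free_scene.shape)
        local_truth = obj.mask[int(y0) : int(math.ceil(y1)), int(x0) : int(math.ceil(x1))]
        iou = (mask & local_truth).sum() / (mask | local_truth).sum()
        assert iou > 0.9

    def test_neighbor_fragment_removed(self):
        # target bar centered in the crop plus a corner fragment of a neighbor
        img = np.full((100, 100, 3), 236, np.uint8)
        img[45:55, 20:80] = 60        # target
        img[0:12, 0:12] = 60          # intruding neighbor corner
        boxmain = DetectionBox.from_xyxy(0, 15, 40, 85, 60, shape=(100, 100))
        mask = lwc.crop_and_select(img, DetectionBox(0, 0.5, 0.5, 1.0, 1.0))
        ys, xs = np.nonzero(mask)
        assert ys.min() > 20  # the corner fragment is gone
        assert mask.sum() == pytest.approx(600, rel=0.05)

    def test_equal_distance_tie_prefers_larger_area(self):
        img = np.full((60, 100, 3), 236, np.uint8)
        img[28:32, 10:30] = 60   # left blob, smaller
        img[24:36, 70:90] = 60   # right blob, larger, same centroid distance
        mask = lwc.crop_and_select(img, DetectionBox(0, 0.5, 0.5, 1.0, 1.0))
        ys, xs = np.nonzero(mask)
        assert xs.mean() > 50

    def test_uniform_crop_raises(self):
        img = np.full((50, 50, 3), 236, np.uint8)
        with pytest.raises(lwc.EmptyObjectError):
            lwc.crop_and_select(img, DetectionBox(0, 0.5, 0.5, 0.5, 0.5))


class TestRotateToHorizontal:
    def test_axis_aligned_bar_identity(self):
        mask = np.zeros((60, 120), bool)
        mask[20:40, 10:110] = True
        rc = lwc.rotate_to_horizontal(mask)
        assert rc.x1 == pytest.approx(100, abs=1)
        assert rc.y1 == pytest.approx(20, abs=1)

    def test_rotated_bar_round_trip(self):
        base = np.zeros((200, 200), bool)
        base[90:110, 40:160] = True
        rotated = ndimage.rotate(base.astype(float), 30, order=1, reshape=True) >= 0.5
        rc = lwc.rotate_to_horizontal(rotated)
        assert rc.x1 == pytest.approx(120, abs=2)
        assert rc.y1 == pytest.approx(20, abs=2)

    def test_square_mask_either_orientation(self):
        mask = np.zeros((50, 50), bool)
        mask[10:40, 10:40] = True
        rc = lwc.rotate_to_horizontal(mask)
        assert rc.x1 == pytest.approx(rc.y1, abs=1.5)

    def test_single_pixel_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        with pytest.raises(ValidationError):
            lwc.rotate_to_horizontal(mask)


class TestSliceStrips:
    def _bar_rc(self):
        mask = np.zeros((20, 100), bool)
        mask[5:15, :] = True
        return lwc.rotate_to_horizontal(mask)

    def test_strip_widths(self):
        rc = self._bar_rc()
        strips = lwc.slice_strips(rc, 10)
        assert len(strips) == 10
        assert all(s.shape[1] == 10 for s in strips)

    def test_partition_conserves_mask(self):
        rc = self._bar_rc()
        strips = lwc.slice_strips(rc, 7)
        assert sum(s.sum() for s in strips) == rc.mask.sum()

    def test_too_many_strips_rejected(self):
        rc = self._bar_rc()
        with pytest.raises(ValidationError):
            lwc.slice_strips(rc, 80)  # < 2 px per strip
        with pytest.raises(ValidationError):
            lwc.slice_strips(rc, 1)


class TestLength:
    def test_straight_capsule(self, calibration):
        mask, _, _ = render_ribbon(10.0, 1.0, 0.0, 25.0, canvas=250)
        length, _, _, _ = measure_mask(mask, calibration)
        assert length == pytest.approx(10.0, rel=0.03)

    def test_semicircular_arc(self, calibration):
        # slender semicircle: centerline pi * r with r = length / pi
        mask, _, _ = render_ribbon(15.0, 0.8, math.pi / 15.0, 0.0, canvas=500)
        length, _, _, _ = measure_mask(mask, calibration)
        assert length == pytest.approx(15.0, rel=0.03)

    @pytest.mark.parametrize("seed", range(4))
    def test_mixed_curvature_family(self, calibration, seed):
        rng = np.random.default_rng(seed)
        L = float(rng.uniform(8, 30))
        W = float(rng.uniform(1, min(3.0, L / 4)))
        curv = float(rng.uniform(-1, 1)) * math.radians(150) / L
        mask, _, _ = render_ribbon(L, W, curv, float(rng.uniform(0, 360)))
        length, _, _, _ = measure_mask(mask, calibration)
        assert length == pytest.approx(L, rel=0.05)

    def test_arc_at_least_chord(self, calibration):
        for seed in range(5):
            rng = np.random.default_rng(seed + 100)
            L = float(rng.uniform(8, 25))
            mask, _, _ = render_ribbon(L, 1.5, float(rng.uniform(-0.1, 0.1)), float(rng.uniform(0, 180)))
            rc = lwc.rotate_to_horizontal(mask)
            _, fit = lwc.length_of(rc, 30, calibration)
            assert fit.arc_length_px >= fit.chord_px - 1e-9

    def test_too_few_strips_error(self, calibration):
        mask = np.zeros((20, 30), bool)
        mask[8:12, 5:25] = True
        rc = lwc.rotate_to_horizontal(mask)
        empty_rc = lwc.RotatedCrop(mask=np.zeros_like(rc.mask), x1=rc.x1, y1=rc.y1, angle_deg=0.0)
        with pytest.raises(ValidationError):
            lwc.length_of(empty_rc, 5, calibration)


class TestWidth:
    def test_straight_bar_width(self, calibration):
        mask, _, _ = render_ribbon(10.0, 1.0, 0.0, 0.0, canvas=250)
        _, width, _, _ = measure_mask(mask, calibration)
        assert width * 10 == pytest.approx(10.0, abs=1.0)  # +- 1 px

    def test_per_strip_diameter_matches_exhaustive_search(self):
        # the per-strip maximum-inscribed-circle radius from the EDT must
        # equal brute-force search over all interior centers
        rng = np.random.default_rng(0)
        for trial in range(5):
            mask = np.zeros((48, 64), bool)
            cy, cx = rng.integers(14, 34), rng.integers(20, 44)
            yy, xx = np.mgrid[0:48, 0:64]
            mask |= ((yy - cy) ** 2 / rng.uniform(20, 80) + (xx - cx) ** 2 / rng.uniform(80, 300)) <= 1
            rc = lwc.RotatedCrop(mask=mask, x1=float(mask.shape[1]), y1=float(mask.shape[0]), angle_deg=0.0)
            dist = rc.distance_transform()
            ys, xs = np.nonzero(mask)
            bg = np.stack(np.nonzero(~mask), axis=1)
            from scipy.spatial import cKDTree

            tree = cKDTree(bg)
            edges = np.round(np.linspace(0, mask.shape[1], 8 + 1)).astype(int)
            for i in range(8):
                sel = (xs >= edges[i]) & (xs < edges[i + 1])
                if not sel.any():
                    continue
                brute = tree.query(np.stack([ys[sel], xs[sel]], axis=1))[0].max()
                assert dist[:, edges[i] : edges[i + 1]].max() == pytest.approx(brute, abs=1e-9)

    def test_constant_width_arc(self, calibration):
        mask, _, _ = render_ribbon(18.0, 1.6, 0.08, 40.0, canvas=400)
        _, width, _, _ = measure_mask(mask, calibration)
        assert width == pytest.approx(1.6, rel=0.15)

    def test_diameters_bounded_by_rect_short_side(self, calibration):
        mask, _, _ = render_ribbon(12.0, 2.0, 0.06, 10.0, canvas=350)
        rc = lwc.rotate_to_horizontal(mask)
        _, wp = lwc.width_of(rc, 30, calibration)
        assert (wp.diameters_px <= rc.y1 + 1e-9).all()
        assert wp.mean_diameter_px == pytest.approx(wp.diameters_px.mean())


class TestInvariances:
    def test_rotation_invariance(self, calibration):
        lengths, widths = [], []
        for deg in range(0, 180, 10):
            mask, _, _ = render_ribbon(12.0, 1.2, 0.08, float(deg), canvas=300)
            length, width, _, _ = measure_mask(mask, calibration)
            lengths.append(length)
            widths.append(width)
        assert (max(lengths) - min(lengths)) / np.mean(lengths) < 0.03
        assert (max(widths) - min(widths)) / np.mean(widths) < 0.08

    def test_scale_equivariance(self):
        results = {}
        for ppmm in (10.0, 20.0):
            cal = lwc.calibrate(9 * ppmm, 9.0)
            mask, _, _ = render_ribbon(14.0, 1.4, 0.07, 30.0, ppmm=ppmm, canvas=int(60 * ppmm))
            length, width, _, _ = measure_mask(mask, cal)
            results[ppmm] = (length, width)
        assert results[20.0][0] == pytest.approx(results[10.0][0], rel=0.02)
        assert results[20.0][1] == pytest.approx(results[10.0][1], rel=0.06)


class TestMeasureScene:
    def test_single_known_ribbon(self, calibration):
        spec = sg.RibbonSpec("G", 14.0, 1.5, 0.05, center=(150.0, 150.0), rotation_deg=20.0, ppmm=10.0)
        sc = sg.generate_scene(specs=[spec], with_block=False, shadow_strength=0.0, seed=1, canvas=(400, 400), ppmm=10.0)
        truths = {oid: (l, w) for oid, l, w in sc.truths}
        df = lwc.measure_scene(sc.image, sc.boxes, calibration, n=50, truths=truths)
        assert len(df) == 1 and df["error"].isna().all()
        assert abs(df["rel_err_len_pct"].iloc[0]) < 5
        assert abs(df["rel_err_wid_pct"].iloc[0]) < 15

    def test_empty_box_list(self, calibration, shadow_free_scene):
        df = lwc.measure_scene(shadow_free_scene.image, [], calibration)
        assert len(df) == 0

    def test_aggregate_report_structure(self, calibration):
        sc = sg.generate_scene(
            n_per_class={c: 2 for c in "YGPZ"}, shadow_strength=0.0, seed=17, canvas=(900, 900), ppmm=10
        )
        truths = {oid: (l, w) for oid, l, w in sc.truths}
        df = lwc.measure_scene(sc.image, sc.boxes, calibration, n=50, truths=truths)
        agg = lwc.aggregate_report(df, truths)
        assert list(agg["sample"]) == ["Total-Y", "Total-G", "Total-P", "Total-Z", "Total"]
        assert agg["n_objects"].iloc[-1] == 8

    def test_failures_recorded_not_raised(self, calibration):
        img = np.full((100, 100, 3), 236, np.uint8)  # nothing to measure
        df = lwc.measure_scene(img, [DetectionBox(0, 0.5, 0.5, 0.4, 0.4)], calibration)
        assert len(df) == 1
        assert df["error"].notna().all()
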