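"""Detection-network components: IoU/CIoU oracles, structure, and smoke training."""

import math

import numpy as np
import pytest

from shredkit import model as M
from shredkit import nn
from shredkit.io import ValidationError


def ciou_oracle(b, bgt):
    """Independent scalar CIoU recomputation, written directly from the
    definition: 1 - IoU + center-distance/diagonal ratio + weighted
    aspect-consistency penalty."""
    ax0, ay0, ax1, ay1 = b
    bx0, by0, bx1, by1 = bgt
    inter_w = min(ax1, bx1) - max(ax0, bx0)
    inter_h = min(ay1, by1) - max(ay0, by0)
    inter = max(inter_w, 0.0) * max(inter_h, 0.0)
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    iou_v = inter / (area_a + area_b - inter)
    cx_a, cy_a = (ax0 + ax1) / 2, (ay0 + ay1) / 2
    cx_b, cy_b = (bx0 + bx1) / 2, (by0 + by1) / 2
    rho2 = (cx_a - cx_b) ** 2 + (cy_a - cy_b) ** 2
    c2 = (max(ax1, bx1) - min(ax0, bx0)) ** 2 + (max(ay1, by1) - min(ay0, by0)) ** 2
    v = 4.0 / math.pi**2 * (math.atan((bx1 - bx0) / (by1 - by0)) - math.atan((ax1 - ax0) / (ay1 - ay0))) ** 2
    a = v / ((1.0 - iou_v) + v) if v > 0 else 0.0
    return 1.0 - iou_v + rho2 / c2 + a * v


def random_boxes(rng, n):
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, 50, 2)
        w, h = rng.uniform(0.5, 40, 2)
        out.append((x0, y0, x0 + w, y0 + h))
    return out


class TestIoU:
    def test_identical_boxes(self):
        assert M.iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert M.iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_hand_computed_overlap(self):
        # inter 1, union 4 + 4 - 1 = 7
        assert M.iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for a, b in zip(random_boxes(rng, 50), random_boxes(rng, 50)):
            assert M.iou(a, b) == pytest.approx(M.iou(b, a), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            M.iou((0, 0, 0, 1), (0, 0, 1, 1))


class TestCIoU:
    def test_identical_boxes_zero(self):
        assert M.ciou_loss((1, 2, 4, 7), (1, 2, 4, 7)) == 0.0

    def test_concentric_equal_aspect(self):
        # same center, same aspect ratio: distance and aspect terms vanish
        b = (4, 4, 6, 6)
        bgt = (2, 2, 8, 8)
        assert M.ciou_loss(b, bgt) == pytest.approx(1.0 - M.iou(b, bgt), abs=1e-12)

    def test_matches_independent_oracle_on_1000_pairs(self):
        rng = np.random.default_rng(123)
        preds = random_boxes(rng, 1000)
        gts = random_boxes(rng, 1000)
        for b, bgt in zip(preds, gts):
            assert M.ciou_loss(b, bgt) == pytest.approx(ciou_oracle(b, bgt), abs=1e-9)

    def test_nonnegative_and_zero_iff_identical(self):
        rng = np.random.default_rng(5)
        for b, bgt in zip(random_boxes(rng, 200), random_boxes(rng, 200)):
            loss = M.ciou_loss(b, bgt)
            assert loss >= 0.0
            if b != bgt:
                assert loss > 0.0

    def test_differentiable_version_matches_scalar(self):
        rng = np.random.default_rng(9)
        for b, bgt in zip(random_boxes(rng, 20), random_boxes(rng, 20)):
            bt = [nn.Tensor(np.float64(v), requires_grad=True) for v in b]
            assert float(M.ciou_loss_t(bt, bgt).data) == pytest.approx(M.ciou_loss(b, bgt), abs=1e-5)


class TestReIBlock:
    def test_forward_shape(self):
        block = M.build_re_i_block(16, 32, seed=0)
        out = block(nn.Tensor(np.random.default_rng(0).normal(size=(1, 16, 16, 16))))
        assert out.shape == (1, 32, 16, 16)

    def test_skip_path_contributes(self):
        rng = np.random.default_rng(1)
        x = nn.Tensor(rng.normal(size=(1, 16, 8, 8)))
        block = M.build_re_i_block(16, 16, seed=0)
        with_skip = block(x).data.copy()
        block.skip = nn.Conv2d(16, 16, 1, rng=np.random.default_rng(2), zero_init=True)  # ablate identity
        without_skip = block(x).data
        assert not np.allclose(with_skip, without_skip)

    def test_parameter_count_analytic(self):
        cin, cout = 16, 32
        mid = cout // 2
        block = M.build_re_i_block(cin, cout, seed=0)
        expected = (
            (cin * mid + mid)            # 1x1 reduce
            + 2 * (mid * mid * 9 + mid)  # two 3x3 taps
            + (cin * mid + mid)          # 1x1 input projection
            + (4 * mid * cout + cout)    # 1x1 fusion of the concat
            + (cin * cout + cout)        # projected skip (cin != cout)
        )
        assert block.count_parameters() == expected

    def test_same_channels_identity_skip_has_no_params(self):
        b1 = M.build_re_i_block(32, 32, seed=0)
        assert b1.skip is None


class TestBackbone:
    def test_tap_strides_at_256(self):
        bb = M.build_backbone(M.BackboneConfig(stage_channels=(16, 32, 64, 128)), seed=0)
        taps = bb(nn.Tensor(np.random.default_rng(0).normal(size=(1, 3, 256, 256))))
        assert taps["p3"].shape[2:] == (32, 32)      # stride 8
        assert taps["p4"].shape[2:] == (16, 16)      # stride 16
        assert taps["stage4"].shape[2:] == (8, 8)    # stride 32

    def test_compressed_has_fewer_parameters(self):
        ch = (64, 128, 256, 512)
        small = M.build_backbone(M.BackboneConfig(block_counts=(1, 2, 2, 1), stage_channels=ch))
        big = M.build_backbone(M.BackboneConfig(block_counts=(3, 4, 6, 3), stage_channels=ch))
        assert small.count_parameters() < big.count_parameters()

    def test_rebuild_identical_parameter_count(self):
        cfg = M.BackboneConfig(stage_channels=(16, 32, 64, 128))
        assert M.build_backbone(cfg, seed=0).count_parameters() == M.build_backbone(cfg, seed=0).count_parameters()

    def test_indivisible_input_rejected(self):
        bb = M.build_backbone(M.BackboneConfig(stage_channels=(8, 16, 32, 64)), seed=0)
        with pytest.raises(ValidationError):
            bb(nn.Tensor(np.zeros((1, 3, 100, 100))))


class TestSPPFCSPC:
    def test_serial_equals_parallel_pools(self):
        sp = M.build_sppfcspc(16, seed=0)
        x = nn.Tensor(np.random.default_rng(3).normal(size=(1, 16, 12, 12)))
        serial = sp(x).data.copy()
        sp.pool_mode = "parallel"
        parallel = sp(x).data
        assert np.allclose(serial, parallel, atol=1e-6)

    def test_shape_preserved(self):
        sp = M.build_sppfcspc(24, seed=1)
        x = nn.Tensor(np.random.default_rng(4).normal(size=(1, 24, 10, 14)))
        assert sp(x).shape == (1, 24, 10, 14)

    def test_parameter_count_independent_of_pool_mode(self):
        a = M.build_sppfcspc(16, seed=0, pool_mode="serial")
        b = M.build_sppfcspc(16, seed=0, pool_mode="parallel")
        assert a.count_parameters() == b.count_parameters()


class TestDecoupledHead:
    def test_output_layout(self):
        head = M.build_decoupled_head(32, n_classes=4, n_anchors=3, seed=0)
        out = head(nn.Tensor(np.random.default_rng(0).normal(size=(1, 32, 8, 8))))
        assert out.shape == (1, 27, 8, 8)  # 3 anchors x (4+1+4)
        assert out.data.reshape(1, 3, 9, 8, 8).shape == (1, 3, 9, 8, 8)

    def test_branches_have_disjoint_parameters(self):
        head = M.build_decoupled_head(32, 4, 3, seed=0)
        out = head(nn.Tensor(np.random.default_rng(1).normal(size=(1, 32, 8, 8))))
        cls_channels = out.reshape(1, 3, 9, 8, 8)[:, :, 5:, :, :]
        (cls_channels**2.0).sum().backward()
        reg_params = head.reg_branch.parameters() + head.reg_out.parameters() + head.obj_out.parameters()
        assert all(p.grad is None or not p.grad.any() for p in reg_params)
        shared = head.reduce.parameters()
        assert any(p.grad is not None and p.grad.any() for p in shared)

    def test_zero_init_zero_output(self):
        head = M.build_decoupled_head(8, 4, 3, seed=0, zero_init=True)
        out = head(nn.Tensor(np.zeros((1, 8, 4, 4))))
        assert not out.data.any()

    def test_invalid_classes(self):
        with pytest.raises(ValidationError):
            M.build_decoupled_head(8, 0, 3)


@pytest.fixture(scope="module")
def scenes():
    return M.make_smoke_scenes(4, seed=11)


class TestSmokeTrain:
    def test_loss_decreases(self, scenes):
        trace = M.smoke_train(scenes, epochs=6, seed=0)
        assert np.isfinite(trace).all()
        assert trace[-1] < trace[0]

    def test_deterministic_trace(self, scenes):
        a = M.smoke_train(scenes, epochs=2, seed=3)
        b = M.smoke_train(scenes, epochs=2, seed=3)
        assert a == b

    def test_too_few_scenes_rejected(self, scenes):
        with pytest.raises(ValidationError):
            M.smoke_train(scenes[:2], epochs=1)
        with pytest.raises(ValidationError):
            M.smoke_train([], epochs=1)

    def test_weight_save_load_round_trip(self, scenes, tmp_path):
        net = M.DetectionModel(M.SMOKE_CONFIG, seed=0)
        path = str(tmp_path / "w.npz")
        M.save_weights(net, path)
        net2 = M.DetectionModel(M.SMOKE_CONFIG, seed=99)
        M.load_weights(net2, path)
        x = nn.Tensor(np.random.default_rng(0).normal(size=(1, 3, 64, 64)).astype(np.float32))
        assert np.allclose(net(x)[0].data, net2(x)[0].data)
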