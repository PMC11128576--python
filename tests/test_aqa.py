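"""Quality network: nuance, CAM, quality losses, MOS scaling, and the
dual-stem VGG11-style architecture."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from g2npan.aqa import (AQAConfig, AQANetwork, compute_cam, compute_nuance,
                        denormalize_mos, loss_aqa, loss_cam, loss_quality,
                        normalize_mos, severity_to_cam_target, sigmoid_map)
from g2npan.discriminator import quality_weight
from g2npan.nn import Tensor


class TestNuance:
    def test_identical_images_give_zero(self, rng):
        x = rng.random((4, 4, 3))
        assert not compute_nuance(x, x).any()

    def test_elementwise_difference(self):
        a = np.full((2, 2, 3), 0.3)
        b = np.full((2, 2, 3), 0.7)
        assert np.allclose(compute_nuance(b, a), 0.4)

    def test_symmetry(self, rng):
        a, b = rng.random((4, 4, 3)), rng.random((4, 4, 3))
        assert np.array_equal(compute_nuance(a, b), compute_nuance(b, a))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            compute_nuance(rng.random((4, 4, 3)), rng.random((8, 8, 3)))

    def test_tensor_path_differentiable(self, rng):
        a = Tensor(rng.random((1, 3, 4, 4)), requires_grad=True)
        b = Tensor(rng.random((1, 3, 4, 4)))
        compute_nuance(a, b).sum().backward()
        assert np.all(np.abs(a.grad) == 1)  # d|a-b|/da = sign(a-b)


class TestCam:
    def test_single_channel_unit_weight_is_normalized_copy(self, rng):
        f = rng.random((4, 4, 1))
        out = compute_cam(f, np.ones(1))
        expect = (f[..., 0] - f.min()) / (f.max() - f.min())
        assert np.allclose(out, expect, atol=1e-12)

    def test_cancellation_normalizes_to_zero(self, rng):
        f1 = rng.random((4, 4))
        f = np.stack([f1, f1], axis=-1)
        assert not compute_cam(f, np.array([1.0, -1.0])).any()

    def test_matches_double_loop_oracle(self, rng):
        f = rng.normal(size=(4, 4, 8))
        w = rng.normal(size=8)
        oracle = np.zeros((4, 4))
        for x in range(4):
            for y in range(4):
                for j in range(8):
                    oracle[x, y] += w[j] * f[x, y, j]
        assert np.abs(compute_cam(f, w, normalize=False) - oracle).max() < 1e-6

    def test_weight_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            compute_cam(rng.random((4, 4, 8)), np.ones(5))


class TestSigmoidMap:
    def test_symmetry_point(self):
        assert sigmoid_map(0.0) == pytest.approx(0.5)

    def test_closed_form_at_log3(self):
        assert sigmoid_map(np.log(3)) == pytest.approx(0.75, abs=1e-12)

    @given(st.floats(-30, 30))
    def test_complement_identity(self, x):
        assert sigmoid_map(x) + sigmoid_map(-x) == pytest.approx(1.0, abs=1e-9)


class TestQualityLoss:
    def test_closed_form(self):
        val = loss_quality(Tensor(np.zeros(1)), np.ones(1))
        assert val.item() == pytest.approx(np.log(2), abs=1e-6)

    def test_minimum_at_matching_sigmoid(self):
        # q_t = 0.5: grid search over q_pre confirms the minimum at 0
        grid = np.linspace(-4, 4, 401)
        vals = [loss_quality(Tensor([z]), np.array([0.5])).item()
                for z in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(0.0, abs=0.02)
        assert min(vals) == pytest.approx(np.log(2), abs=1e-6)

    def test_stationary_gradient_when_prediction_matches(self, rng):
        z = rng.normal(size=4)
        q = Tensor(z, requires_grad=True)
        loss_quality(q, sigmoid_map(z)).backward()
        assert np.abs(q.grad).max() < 1e-6

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            loss_quality(Tensor(np.zeros(1)), np.array([1.2]))


class TestCamLoss:
    def test_identity_gives_zero(self, rng):
        f = rng.random((2, 4, 4))
        assert loss_cam(f, f).item() == 0

    def test_constant_maps_closed_form(self):
        a = np.full((1, 4, 4), 0.2)
        b = np.full((1, 4, 4), 0.5)
        assert loss_cam(a, b).item() == pytest.approx(0.3, abs=1e-6)

    def test_bounded_by_one_for_unit_maps(self, rng):
        a, b = rng.random((2, 4, 4)), rng.random((2, 4, 4))
        assert loss_cam(a, b).item() <= 1.0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            loss_cam(rng.random((1, 4, 4)), rng.random((1, 8, 8)))


class TestTotalLoss:
    def test_weighting(self):
        assert loss_aqa(0.3, 0.7, phi=1.0) == pytest.approx(1.0)
        assert loss_aqa(0.3, 0.7, phi=0.0) == pytest.approx(0.7)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            loss_aqa(0.1, 0.1, phi=-1)


class TestMosScaling:
    @pytest.mark.parametrize("mos,score", [(1.0, 0.0), (3.0, 0.5), (5.0, 1.0)])
    def test_endpoints_and_midpoint(self, mos, score):
        assert normalize_mos(mos) == pytest.approx(score)
        assert denormalize_mos(score) == pytest.approx(mos)

    @given(st.floats(1, 5))
    def test_round_trip(self, mos):
        assert denormalize_mos(normalize_mos(mos)) == pytest.approx(mos,
                                                                    abs=1e-12)

    @given(st.floats(0, 1))
    def test_weight_threshold_composition(self, s):
        # MOS >= 3 exactly when the normalized score is >= 0.5
        assert quality_weight(denormalize_mos(s)) == (1 if s >= 0.5 else 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_mos(5.5)
        with pytest.raises(ValueError):
            denormalize_mos(-0.1)


def small_aqa(in_size=32, **kw):
    cfg = AQAConfig(in_size=in_size, base_width=8, stem_channels=4,
                    flast_channels=8, hidden=16, **kw)
    return AQANetwork(cfg, np.random.default_rng(0))


class TestNetwork:
    def test_output_shapes_at_full_resolution(self, rng):
        net = small_aqa(in_size=128).eval()
        x = rng.random((2, 3, 128, 128), dtype=np.float32)
        s = rng.random((2, 3, 128, 128), dtype=np.float32)
        fl = rng.random((2, 8, 32, 32), dtype=np.float32)
        out = net(x, s, fl)
        assert out.q_pre.shape == (2,)
        assert np.all(np.isfinite(out.q_pre.data))
        # 5 pooling stages: 128 -> 4, the standard VGG11 reduction
        assert out.f_cam.shape == (2, 4, 4)
        assert out.f_cam.data.min() >= 0 and out.f_cam.data.max() <= 1
        assert np.allclose(out.q_sigmoid.data,
                           1 / (1 + np.exp(-out.q_pre.data)), atol=1e-6)

    def test_trunk_only_ablation(self, rng):
        net = small_aqa(use_nuance=False, use_flast=False, use_cam=False).eval()
        out = net(rng.random((2, 3, 32, 32), dtype=np.float32))
        assert out.q_pre.shape == (2,)

    def test_missing_f_last_rejected(self, rng):
        net = small_aqa().eval()
        x = rng.random((1, 3, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError, match="F_last"):
            net(x, x)

    def test_missing_nuance_rejected(self, rng):
        net = small_aqa().eval()
        with pytest.raises(ValueError, match="I_sub"):
            net(rng.random((1, 3, 32, 32), dtype=np.float32))

    def test_deterministic_in_eval_mode(self, rng):
        net = small_aqa().eval()
        x = rng.random((2, 3, 32, 32), dtype=np.float32)
        s = rng.random((2, 3, 32, 32), dtype=np.float32)
        fl = rng.random((2, 8, 8, 8), dtype=np.float32)
        a, b = net(x, s, fl), net(x, s, fl)
        assert np.array_equal(a.q_pre.data, b.q_pre.data)
        assert np.array_equal(a.f_cam.data, b.f_cam.data)

    def test_gradients_reach_both_stems_and_trunk(self, rng):
        net = small_aqa().train()
        x = rng.random((2, 3, 32, 32), dtype=np.float32)
        s = rng.random((2, 3, 32, 32), dtype=np.float32)
        fl = rng.random((2, 8, 8, 8), dtype=np.float32)
        out = net(x, s, fl)
        target_cam = rng.random((2, 4, 4))
        total = loss_aqa(loss_cam(out.f_cam, target_cam),
                         loss_quality(out.q_pre, np.full(2, 0.3)), phi=1.0)
        total.backward()
        for mod in (net.stem_org, net.stem_sub, net.trunk_convs[0],
                    net.trunk_convs[-1], net.fc1, net.fc2):
            assert mod.weight.grad is not None
            assert np.abs(mod.weight.grad).max() > 0

    def test_pool_plan_adapts_to_input_size(self):
        # 32x32 input: only three of VGG11's five pools fit before 4x4
        net32 = small_aqa(in_size=32)
        net128 = small_aqa(in_size=128)
        assert sum(net32._pool_after) == 3
        assert sum(net128._pool_after) == 5


class TestCamTarget:
    def test_block_mean_downsample_and_normalization(self):
        sev = np.zeros((1, 32, 32), np.float32)
        sev[0, :8, :8] = 1.0  # one hot quadrant
        out = severity_to_cam_target(sev, 4)
        assert out.shape == (1, 4, 4)
        assert out[0, 0, 0] == pytest.approx(1.0)
        assert out[0, 3, 3] == pytest.approx(0.0)

    def test_constant_map_goes_to_zero(self):
        out = severity_to_cam_target(np.full((2, 32, 32), 0.7), 4)
        assert not out.any()
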