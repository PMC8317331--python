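"""Architectures: factorized anisotropic convolution, both ResNet branches,
and the two ensemble strategies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dbtmc.networks import (
    Aniso3dNetConfig,
    AnisoConvSpec,
    EnsembleConfig,
    FeatureEnsembleHead,
    aniso_conv_forward,
    aniso_param_count,
    build_aniso_resnet3d,
    build_resnet34_2d,
    decision_ensemble,
    feature_ensemble_forward,
    isotropic_param_count,
)
from dbtmc.nn.losses import softmax_cross_entropy


class TestAnisoConv:
    def test_unit_stride_preserves_spatial_shape(self):
        spec = AnisoConvSpec(k=3, c_in=2, c_temp=2, c_out=5)
        x = np.random.default_rng(0).normal(size=(1, 10, 9, 6, 2))
        y = aniso_conv_forward(x, spec)
        assert y.shape == (1, 10, 9, 6, 5)

    def test_parameter_count_is_4_9_of_isotropic(self):
        spec = AnisoConvSpec(k=3, c_in=64, c_temp=64, c_out=64)
        assert aniso_param_count(spec) == 49_152
        assert isotropic_param_count(spec) == 110_592
        assert aniso_param_count(spec) * 9 == isotropic_param_count(spec) * 4

    def test_identity_kernels_give_identity(self):
        c, k = 3, 3
        k1 = np.zeros((c, c, k, k), dtype=np.float32)
        k2 = np.zeros((c, c, k), dtype=np.float32)
        for i in range(c):
            k1[i, i, k // 2, k // 2] = 1.0
            k2[i, i, k // 2] = 1.0
        spec = AnisoConvSpec(k=k, c_in=c, c_temp=c, c_out=c, k1=k1, k2=k2)
        x = np.random.default_rng(1).normal(size=(2, 6, 5, 4, c))
        assert np.allclose(aniso_conv_forward(x, spec), x, atol=1e-5)

    def test_channel_mismatch_errors(self):
        spec = AnisoConvSpec(k=3, c_in=4, c_temp=4, c_out=4)
        with pytest.raises(ValueError):
            aniso_conv_forward(np.zeros((1, 4, 4, 4, 2)), spec)

    def test_bad_kernel_shape_rejected(self):
        with pytest.raises(ValueError):
            AnisoConvSpec(k=3, c_in=2, c_temp=2, c_out=2,
                          k1=np.zeros((2, 2, 5, 5)))


class TestAnisoResNet3d:
    def test_desk_forward_shape_and_channels(self):
        cfg = Aniso3dNetConfig.desk()
        net = build_aniso_resnet3d(cfg, seed=0)
        y = net.forward(np.zeros((2, 1, 8, 32, 32), np.float32))
        assert y.shape == (2, 2)
        assert net.last_features.shape == (2, cfg.block_channels[-1])

    def test_full_config_final_channels_512(self):
        cfg = Aniso3dNetConfig()
        assert cfg.block_channels[-1] == 512
        assert cfg.block_modules == (3, 4, 6, 3)

    @pytest.mark.parametrize("n_slices", [4, 6, 8, 10, 12])
    def test_depth_preserved_through_trunk(self, n_slices):
        """The slice axis is never strided: trunk output depth equals input
        depth for every tested slab size."""
        net = build_aniso_resnet3d(Aniso3dNetConfig.desk(), seed=0)
        x = np.zeros((1, 1, n_slices, 32, 32), np.float32)
        feat = net.trunk.forward(x, train=False)
        assert feat.shape[2] == n_slices
        assert net.forward(x).shape == (1, 2)

    def test_decreasing_channels_rejected(self):
        with pytest.raises(ValueError):
            Aniso3dNetConfig(block_modules=(1, 1), block_channels=(64, 32))

    def test_eval_forward_deterministic(self):
        net = build_aniso_resnet3d(Aniso3dNetConfig.desk(), seed=3)
        x = np.random.default_rng(0).normal(size=(1, 1, 4, 16, 16)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))


def _resnet34_expected_tensor_count():
    """Closed-form tensor count of the canonical 34-layer residual net:
    per module 2 convs + 2 BNs (gamma, beta) = 6 tensors, plus a projection
    conv + BN (3 tensors) at each of the 3 block transitions, the stem
    conv + BN (3) and the final linear (2)."""
    modules = [3, 4, 6, 3]
    per_module = 2 * 1 + 2 * 2  # conv weights + BN gamma/beta
    projections = 3 * (1 + 2)
    stem = 1 + 2
    fc = 2
    return sum(modules) * per_module + projections + stem + fc


def _resnet34_expected_param_count(in_channels=1, n_classes=2):
    ch = [64, 128, 256, 512]
    mods = [3, 4, 6, 3]
    total = in_channels * 64 * 7 * 7 + 2 * 64  # stem conv + BN
    c_prev = 64
    for c, m in zip(ch, mods):
        for i in range(m):
            total += c_prev * c * 9 + 2 * c  # conv1 + bn1
            total += c * c * 9 + 2 * c  # conv2 + bn2
            if c_prev != c:
                total += c_prev * c + 2 * c  # projection + bn
            c_prev = c
    total += 512 * n_classes + n_classes
    return total


class TestResNet34:
    def test_forward_shape_and_feature_length(self):
        net = build_resnet34_2d(block_modules=(1, 1, 1, 1),
                                block_channels=(8, 16, 32, 64), seed=0)
        y = net.forward(np.zeros((2, 1, 64, 64), np.float32))
        assert y.shape == (2, 2)
        assert net.last_features.shape == (2, 64)

    def test_canonical_tensor_and_parameter_counts(self):
        net = build_resnet34_2d(seed=0)
        assert len(net.params()) == _resnet34_expected_tensor_count()
        total = sum(p.value.size for p in net.params())
        assert total == _resnet34_expected_param_count()
        assert net.feat_dim == 512

    def test_mismatched_block_config_rejected(self):
        with pytest.raises(ValueError):
            build_resnet34_2d(block_modules=(1, 1), block_channels=(8,))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_outputs(self, tmp_path):
        net = build_resnet34_2d(block_modules=(1, 1, 1, 1),
                                block_channels=(4, 8, 8, 8), seed=1)
        x = np.random.default_rng(0).normal(size=(1, 1, 32, 32)).astype(np.float32)
        y0 = net.forward(x)
        net.save(tmp_path / "ck.npz")
        other = build_resnet34_2d(block_modules=(1, 1, 1, 1),
                                  block_channels=(4, 8, 8, 8), seed=99)
        other.load(tmp_path / "ck.npz")
        assert np.allclose(other.forward(x), y0)


class TestFeatureEnsemble:
    def test_zero_features_give_bias_logits(self):
        head = FeatureEnsembleHead(8, 8, seed=0)
        z = np.zeros((1, 8))
        logits = feature_ensemble_forward(z, z, head)
        assert np.allclose(logits, head.fc.b.value)

    def test_concat_order_2d_first(self):
        head = FeatureEnsembleHead(2, 2, seed=0)
        head.fc.w.value = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]],
                                   dtype=np.float32)
        head.fc.b.value[:] = 0
        logits = feature_ensemble_forward(np.array([[5.0, 0]]),
                                          np.array([[7.0, 0]]), head)
        assert logits.tolist() == [[5.0, 7.0]]

    def test_length_mismatch_errors(self):
        head = FeatureEnsembleHead(8, 8, seed=0)
        with pytest.raises(ValueError):
            feature_ensemble_forward(np.zeros((1, 4)), np.zeros((1, 8)), head)

    def test_gradient_reaches_both_branches(self):
        head = FeatureEnsembleHead(4, 4, seed=0)
        f2d = np.random.default_rng(0).normal(size=(3, 4)).astype(np.float32)
        f3d = np.random.default_rng(1).normal(size=(3, 4)).astype(np.float32)
        logits = head.forward(f2d, f3d, train=True)
        _, dlogits = softmax_cross_entropy(logits, np.array([0, 1, 0]))
        d2d, d3d = head.backward(dlogits)
        assert np.abs(d2d).max() > 0
        assert np.abs(d3d).max() > 0


class TestDecisionEnsemble:
    def test_unweighted_average(self):
        out = decision_ensemble([0.4, 0.6], [0.2, 0.8], 0.5)
        assert np.allclose(out, [0.3, 0.7])

    def test_identical_inputs_fixed_point(self):
        p = np.array([0.35, 0.65])
        for w in (0.0, 0.3, 0.5, 0.7, 1.0):
            assert np.allclose(decision_ensemble(p, p, w), p)

    def test_endpoint_weights(self):
        out = decision_ensemble([1.0, 0.0], [0.0, 1.0], 0.3)
        assert np.allclose(out, [0.3, 0.7])

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            decision_ensemble([0.9, 0.3], [0.5, 0.5], 0.5)
        with pytest.raises(ValueError):
            decision_ensemble([0.5, 0.5], [0.5, 0.5], 1.2)

    @given(
        st.floats(0.001, 0.999),
        st.floats(0.001, 0.999),
        st.floats(0.0, 1.0),
    )
    def test_output_is_valid_probability_vector(self, a, b, w):
        out = decision_ensemble([a, 1 - a], [b, 1 - b], w)
        assert np.all(out >= 0)
        assert out.sum() == pytest.approx(1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnsembleConfig(mode="vote")
        with pytest.raises(ValueError):
            EnsembleConfig(weight_2d=1.5)
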