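"""Architecture contracts: tap strides/depths, feature integration, SE gates,
fusion, segmentation head, and thresholding semantics."""

import numpy as np
import pytest

import toothseg as ts
from toothseg import nn
from toothseg.network import PredictionStack, _SEGate


def rand_img(shape=(64, 128), seed=0):
    return np.random.default_rng(seed).random(shape, dtype=np.float32)


class TestEncoder:
    def test_tiny_tap_strides_and_depths(self, tiny_net):
        pyr = tiny_net.encode(rand_img())
        assert pyr.shapes() == [(32, 64, 8), (16, 32, 16), (8, 16, 24),
                                (4, 8, 32), (2, 4, 48)]

    def test_rejects_non_divisible_dims(self, tiny_net):
        with pytest.raises(ValueError, match="divisible by 32"):
            tiny_net.encode(rand_img((60, 100)))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            ts.EncoderConfig(backbone="resnet")


class TestFeatureIntegration:
    def test_pointwise_parameter_count_closed_form(self):
        # a 1x1 convolution from depth 2048 to 128 has 2048*128 + 128 weights
        conv = nn.Conv2d(2048, 128, kernel=1)
        assert conv.n_params == 2048 * 128 + 128

    def test_pointwise_zero_in_zero_out(self):
        conv = nn.Conv2d(16, 8, kernel=1)
        out = conv(nn.Tensor(np.zeros((1, 4, 4, 16))))
        assert (out.data == 0).all()

    def test_constant_pyramid_telescopes(self, tiny_net):
        # with all E_i == 1 and replicating upsampling, F_i counts the number
        # of pyramid levels merged into it: F1=5, F2=4, F3=3, F4=2, F5=1
        c = 4
        E = [nn.Tensor(np.ones((1, 2 ** (5 - i), 2 ** (6 - i), c)))
             for i in range(5)]
        F = tiny_net.integrate_features(E)
        for i, expect in enumerate([5.0, 4.0, 3.0, 2.0, 1.0]):
            assert np.allclose(F[i].data, expect)
            assert F[i].data.shape == E[i].data.shape

    def test_zero_pyramid_stays_zero(self, tiny_net):
        E = [nn.Tensor(np.zeros((1, 2 ** (5 - i), 2 ** (6 - i), 3)))
             for i in range(5)]
        assert all((f.data == 0).all() for f in tiny_net.integrate_features(E))

    def test_f5_equals_e5(self, tiny_net):
        E = [nn.Tensor(np.random.default_rng(i).random((1, 2 ** (5 - i),
                                                        2 ** (6 - i), 4)))
             for i in range(5)]
        F = tiny_net.integrate_features(E)
        assert (F[4].data == E[4].data).all()


class TestSEGate:
    def test_two_channel_toy_oracle(self):
        # K = (4, -2); squeeze averages the channels, expand duplicates:
        # cf = ((4-2)/2, (4-2)/2) = (1, 1), scf = sigmoid(1) = 0.73106,
        # WK = (4, -2) * 0.73106 = (2.92423, -1.46212)   [hand computation]
        gate = _SEGate(2, np.random.default_rng(0))
        gate.squeeze.w.data[:] = np.array([0.5, 0.5]).reshape(1, 1, 2, 1)
        gate.squeeze.b.data[:] = 0
        gate.expand.w.data[:] = np.array([1.0, 1.0]).reshape(1, 1, 1, 2)
        gate.expand.b.data[:] = 0
        K = nn.Tensor(np.array([4.0, -2.0]).reshape(1, 1, 1, 2))
        cf, scf, WK = gate(K)
        assert np.allclose(cf.data, [1.0, 1.0])
        assert np.allclose(scf.data, 0.7310586, atol=1e-6)
        assert np.allclose(WK.data, [2.9242343, -1.4621171], atol=1e-5)

    def test_zero_input_gates_to_zero(self):
        gate = _SEGate(8, np.random.default_rng(1))
        _, scf, WK = gate(nn.Tensor(np.zeros((1, 3, 3, 8))))
        assert (WK.data == 0).all()

    def test_gate_bounded_and_sigmoid_open_interval(self):
        gate = _SEGate(8, np.random.default_rng(2))
        K = nn.Tensor(np.random.default_rng(3).normal(size=(2, 5, 7, 8)) * 10)
        _, scf, WK = gate(K)
        assert (scf.data > 0).all() and (scf.data < 1).all()
        assert (np.abs(WK.data) <= np.abs(K.data) + 1e-7).all()
        assert WK.data.shape == K.data.shape

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ValueError):
            _SEGate(7, np.random.default_rng(0))


class TestDecoderAndHead:
    def test_seib_output_depth_three_branches(self, tiny_net):
        F = nn.Tensor(np.random.default_rng(0).random((1, 8, 16, 32)))
        M = tiny_net._seibs[0](F)
        assert M.data.shape == (1, 8, 16, 3 * 8)

    def test_fusion_concats_depth_blocks_at_finest_size(self, tiny_net):
        bw3 = 24
        consts = [1.0, 2.0, 3.0, 4.0]
        M = [nn.Tensor(np.full((1, 32 // 2 ** i, 64 // 2 ** i, bw3), c))
             for i, c in enumerate(consts)]
        fused = tiny_net.fuse_decoder(M)
        assert fused.data.shape == (1, 32, 64, 4 * bw3)
        for i, c in enumerate(consts):
            assert np.allclose(fused.data[..., i * bw3:(i + 1) * bw3], c)
        # permuting the inputs permutes the depth blocks only
        fused_rev = tiny_net.fuse_decoder(
            [M[0], nn.Tensor(M[1].data * 0 + 9.0), M[2], M[3]])
        assert np.allclose(fused_rev.data[..., bw3:2 * bw3], 9.0)

    def test_zero_input_zero_bias_gives_zero_logits(self):
        net = ts.SEIBEDNetwork(ts.NetworkConfig.tiny(head_bias_init=0.0), seed=0)
        logits = net.forward_tensor(np.zeros((1, 64, 128), dtype=np.float32))
        assert np.allclose(logits.data, 0.0)

    def test_sigmoid_head_shape_and_softmax_normalization(self):
        img = rand_img()
        sig = ts.SEIBEDNetwork(ts.NetworkConfig.tiny(), seed=0).forward(img)
        assert sig.probs.shape == (1, 64, 128, 32)
        assert ((sig.probs > 0) & (sig.probs < 1)).all()
        soft = ts.SEIBEDNetwork(
            ts.NetworkConfig.tiny(activation="softmax"), seed=0).forward(img)
        assert soft.probs.shape == (1, 64, 128, 33)
        assert np.abs(soft.probs.sum(axis=-1) - 1).max() < 1e-5

    def test_zero_logits_activation_values(self):
        net = ts.SEIBEDNetwork(ts.NetworkConfig.tiny(head_bias_init=0.0), seed=0)
        for p in net._head_proj.params():
            p.data[:] = 0
        stack = net.forward(rand_img())
        assert np.allclose(stack.probs, 0.5)
        soft_net = ts.SEIBEDNetwork(
            ts.NetworkConfig.tiny(activation="softmax", head_bias_init=0.0),
            seed=0)
        for p in soft_net._head_proj.params():
            p.data[:] = 0
        stack = soft_net.forward(rand_img())
        assert np.allclose(stack.probs, 1 / 33, atol=1e-6)

    def test_bilinear_upsample_config_matches_shapes(self):
        net = ts.SEIBEDNetwork(ts.NetworkConfig.tiny(upsample="bilinear"), seed=0)
        stack = net.forward(rand_img())
        assert stack.probs.shape == (1, 64, 128, 32)


class TestThresholding:
    def test_strict_inequality_at_boundary(self):
        probs = np.full((1, 4, 4, 32), 0.5)
        stack = PredictionStack(logits=probs, probs=probs, activation="sigmoid")
        assert ts.threshold_predictions(stack, 0.5).sum() == 0

    def test_multilabel_overlap_preserved(self):
        probs = np.zeros((1, 2, 2, 32))
        probs[0, 0, 0, [3, 4]] = 0.9
        stack = PredictionStack(logits=probs, probs=probs, activation="sigmoid")
        out = ts.threshold_predictions(stack, 0.5)
        assert out[0, 0, 0, 3] == 1 and out[0, 0, 0, 4] == 1
        assert out.sum() == 2

    def test_threshold_zero_sets_all_positive(self):
        probs = np.random.default_rng(0).random((1, 4, 4, 32)) * 0.4
        stack = PredictionStack(logits=probs, probs=probs, activation="sigmoid")
        assert (ts.threshold_predictions(stack, 0.0) == 1).all()

    def test_softmax_stack_rejected(self):
        probs = np.full((1, 2, 2, 33), 1 / 33)
        stack = PredictionStack(logits=probs, probs=probs, activation="softmax")
        with pytest.raises(ValueError, match="softmax"):
            ts.threshold_predictions(stack, 0.5)

    def test_softmax_reduction_single_label(self):
        probs = np.full((1, 2, 2, 33), 0.01)
        probs[0, 0, 0, 5] = 0.9
        probs[0, 1, 1, 32] = 0.9  # background
        stack = PredictionStack(logits=probs, probs=probs, activation="softmax")
        out = ts.softmax_to_binary(stack)
        assert out[0, 0, 0, 5] == 1
        assert out[0, 1, 1].sum() == 0
        assert (out.sum(axis=-1) <= 1).all()


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_net, tmp_path):
        img = rand_img(seed=5)
        before = tiny_net.forward(img).probs
        tiny_net.save(tmp_path / "w.npz")
        restored = ts.SEIBEDNetwork.load(tmp_path / "w.npz")
        assert restored.config == tiny_net.config
        assert np.allclose(restored.forward(img).probs, before)
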