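"""Forward-model components: attention, DenseNet shapes, GRU, GAP head."""

import numpy as np
import pytest

from insolenet.model import (
    AttentionLayerParams,
    DenseNetConfig,
    EstimatorNet,
    GruParams,
    HeadParams,
    attention_forward,
    bigru_forward,
    densenet1d_forward,
    extract_attention_weights,
    feature_channels,
    gap_head,
    gru_step,
    min_input_length,
    model_forward,
    temporal_length,
)
from insolenet.nn.autodiff import Tensor
from conftest import TINY_DENSENET

rng = np.random.default_rng(0)


class TestAttentionForward:
    def test_zero_params_give_half(self):
        s = rng.normal(size=(6, 20))
        out = attention_forward(s, AttentionLayerParams(np.zeros((20, 20)),
                                                        np.zeros(20)))
        np.testing.assert_allclose(out.att, 0.5)
        np.testing.assert_allclose(out.s_att, 0.5 * s)

    def test_large_bias_saturates_to_identity(self):
        s = rng.normal(size=(6, 20))
        out = attention_forward(
            s, AttentionLayerParams(np.zeros((20, 20)), np.full(20, 50.0))
        )
        np.testing.assert_allclose(out.att, 1.0, atol=1e-12)
        np.testing.assert_allclose(out.s_att, s, atol=1e-10)

    def test_matches_elementwise_loop(self):
        s = rng.normal(size=(3, 2))
        w = np.array([[0.3, -0.7], [1.1, 0.2]])
        b = np.array([0.05, -0.4])
        out = attention_forward(s, AttentionLayerParams(w, b))
        for tau in range(3):
            for c in range(2):
                pre = b[c] + sum(s[tau, d] * w[d, c] for d in range(2))
                assert out.o[tau, c] == pytest.approx(1 / (1 + np.exp(-pre)))
        for c in range(2):
            assert out.att[c] == pytest.approx(out.o[:, c].mean())
            for tau in range(3):
                assert out.s_att[tau, c] == pytest.approx(out.att[c] * s[tau, c])

    def test_att_in_unit_interval_and_ratio_constant(self):
        s = rng.normal(size=(30, 20)) + 1e-3
        params = AttentionLayerParams(rng.normal(size=(20, 20)), rng.normal(size=20))
        out = attention_forward(s, params)
        assert np.all(out.att > 0) and np.all(out.att < 1)
        ratio = out.s_att / s
        np.testing.assert_allclose(ratio, np.broadcast_to(out.att, ratio.shape))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            attention_forward(np.zeros((3, 5)),
                              AttentionLayerParams(np.zeros((4, 4)), np.zeros(4)))


class TestGruStep:
    def make_params(self, h, nin, scale=0.0):
        return GruParams(*(np.full((h + nin, h), scale) for _ in range(3)))

    def test_all_zero(self):
        p = self.make_params(3, 2)
        np.testing.assert_allclose(gru_step(np.zeros(2), np.zeros(3), p), 0.0)

    def test_zero_weights_halve_state(self):
        p = self.make_params(3, 2)
        v = np.array([0.4, -1.0, 2.0])
        # z = 0.5, candidate = 0 -> new state is v/2
        np.testing.assert_allclose(gru_step(np.ones(2), v, p), 0.5 * v)

    def test_scalar_hand_computation(self):
        wr = np.array([[0.5], [1.0]])
        wz = np.array([[-0.3], [0.2]])
        wh = np.array([[0.7], [-0.4]])
        p = GruParams(wr, wz, wh)
        x, h0 = np.array([2.0]), np.array([0.5])
        r = 1 / (1 + np.exp(-(0.5 * 0.5 + 2.0 * 1.0)))
        z = 1 / (1 + np.exp(-(0.5 * -0.3 + 2.0 * 0.2)))
        cand = np.tanh(r * 0.5 * 0.7 + 2.0 * -0.4)
        expect = (1 - z) * 0.5 + z * cand
        assert gru_step(x, h0, p)[0] == pytest.approx(expect, abs=1e-12)


class TestBigru:
    def test_time_reversal_swaps_directions(self):
        h, nin, T = 4, 3, 3
        fwd = GruParams(*(rng.normal(size=(h + nin, h)) * 0.5 for _ in range(3)))
        bwd = GruParams(*(rng.normal(size=(h + nin, h)) * 0.5 for _ in range(3)))
        x = rng.normal(size=(T, nin))
        out = bigru_forward(x, fwd, bwd)
        flipped = bigru_forward(x[::-1], bwd, fwd)
        # reversing time and swapping direction parameters mirrors the output
        np.testing.assert_allclose(out[:, :h], flipped[::-1, h:], atol=1e-12)
        np.testing.assert_allclose(out[:, h:], flipped[::-1, :h], atol=1e-12)

    def test_single_step(self):
        h, nin = 2, 3
        p = GruParams(*(rng.normal(size=(h + nin, h)) for _ in range(3)))
        x = rng.normal(size=(1, nin))
        out = bigru_forward(x, p, p)
        one = gru_step(x[0], np.zeros(h), p)
        np.testing.assert_allclose(out[0, :h], one)
        np.testing.assert_allclose(out[0, h:], one)

    def test_zero_params_zero_output(self):
        p = GruParams(np.zeros((5, 2)), np.zeros((5, 2)), np.zeros((5, 2)))
        out = bigru_forward(rng.normal(size=(4, 3)), p, p)
        np.testing.assert_allclose(out, 0.0)


class TestGapHead:
    def test_constant_sequence(self):
        h = np.tile(rng.normal(size=3), (5, 1))
        head = HeadParams(rng.normal(size=3), 0.7)
        assert gap_head(h, head) == pytest.approx(h[0] @ head.w_out + 0.7)

    def test_zero_weights_give_bias(self):
        assert gap_head(rng.normal(size=(4, 3)),
                        HeadParams(np.zeros(3), -1.5)) == pytest.approx(-1.5)

    def test_matches_per_step_loop(self):
        f = rng.normal(size=(4, 3))
        head = HeadParams(rng.normal(size=3), 0.2)
        loop = np.mean([f[t] @ head.w_out + head.b_out for t in range(4)])
        assert gap_head(f, head) == pytest.approx(loop, abs=1e-12)

    def test_average_before_or_after_projection(self):
        f = rng.normal(size=(7, 5))
        head = HeadParams(rng.normal(size=5), 0.3)
        assert gap_head(f, head) == pytest.approx(
            f.mean(axis=0) @ head.w_out + head.b_out, abs=1e-12
        )


class TestDenseNetShapes:
    @pytest.mark.parametrize("cfg,t", [
        (DenseNetConfig(), 333),
        (TINY_DENSENET, 67),
        (DenseNetConfig(initial_channels=16, growth_rate=8, layers_per_block=2,
                        n_blocks=3, stem_stride=4), 333),
    ])
    def test_shapes_follow_closed_form(self, cfg, t):
        net_out = densenet1d_forward(
            rng.normal(size=(t, 20)),
            _make_densenet(cfg),
        )
        assert net_out.shape == (temporal_length(t, cfg), feature_channels(cfg))
        assert temporal_length(t, cfg) < t  # pooling strictly compresses

    def test_default_channel_arithmetic(self):
        # 24 -> +48 = 72 -> x0.5 = 36 -> +48 = 84 -> x0.5 = 42 -> +48 = 90
        assert feature_channels(DenseNetConfig()) == 90
        # stem (stride 2, pad 3): 333 -> 167; two stride-2 pools: 83 -> 41
        assert temporal_length(333, DenseNetConfig()) == 41

    def test_too_short_window_reports_minimum(self):
        cfg = DenseNetConfig()
        m = min_input_length(cfg)
        with pytest.raises(ValueError, match="minimum"):
            temporal_length(m - 5, cfg)
        assert temporal_length(m, cfg) >= 1

    def test_zero_input_zero_convs_give_zero_features(self):
        net = _make_densenet(TINY_DENSENET)
        for name, p in net.named_parameters().items():
            if name.endswith(".w") or name.endswith(".b"):
                p.data[...] = 0.0  # conv weights/biases; norms untouched
        out = densenet1d_forward(np.zeros((67, 20)), net)
        np.testing.assert_allclose(out, 0.0)

    def test_random_config_shape_property(self):
        r = np.random.default_rng(5)
        for _ in range(10):
            cfg = DenseNetConfig(
                n_blocks=int(r.integers(1, 4)),
                layers_per_block=int(r.integers(1, 4)),
                growth_rate=int(r.integers(2, 16)),
                initial_channels=int(r.integers(4, 32)),
                stem_stride=int(r.integers(1, 5)),
                compression=float(r.uniform(0.3, 1.0)),
            )
            t = int(r.integers(min_input_length(cfg), 200))
            out = densenet1d_forward(r.normal(size=(t, 20)), _make_densenet(cfg))
            assert out.shape == (temporal_length(t, cfg), feature_channels(cfg))


def _make_densenet(cfg):
    from insolenet.model import DenseNet1d

    return DenseNet1d(np.random.default_rng(1), 20, cfg)


class TestEstimatorNet:
    def make_net(self, **kw):
        kw.setdefault("densenet", TINY_DENSENET)
        kw.setdefault("hidden_size", 8)
        return EstimatorNet(seed=3, **kw)

    def test_all_ones_attention_equals_bypass(self):
        """Forcing att = 1 must reproduce the no-attention forward bit-for-bit."""
        net = self.make_net(attention_enabled=True)
        ablated = self.make_net(attention_enabled=False)
        ablated.load_state_dict(net.state_dict())  # identical downstream weights
        # saturate the attention sigmoid -> att = 1 exactly (within float)
        net.attention.b_in.data[...] = 1e4
        net.attention.w_in.data[...] = 0.0
        x = rng.normal(size=(6, 67, 20))
        net.set_training(False)
        ablated.set_training(False)
        p1, att = net.forward(Tensor(x))
        p2, none_att = ablated.forward(Tensor(x))
        assert none_att is None
        np.testing.assert_allclose(att.data, 1.0)
        np.testing.assert_array_equal(p1.data, p2.data)

    def test_deterministic_forward(self):
        net = self.make_net()
        x = rng.normal(size=(2, 67, 20))
        net.set_training(False)
        a, _ = net.forward(Tensor(x))
        b, _ = net.forward(Tensor(x))
        np.testing.assert_array_equal(a.data, b.data)
        assert np.isfinite(a.data).all()

    def test_model_forward_single_window(self):
        net = self.make_net()
        pred, att = model_forward(net, rng.normal(size=(67, 20)))
        assert np.isfinite(pred)
        assert att.shape == (20,)
        assert np.all((att > 0) & (att < 1))

    def test_wrong_channel_count_raises(self):
        net = self.make_net()
        with pytest.raises(ValueError, match="channels"):
            net.forward(Tensor(np.zeros((1, 67, 19))))


class TestExtractAttentionWeights:
    def test_zero_init_gives_half(self):
        net = EstimatorNet(seed=0, densenet=TINY_DENSENET, hidden_size=8)
        net.attention.w_in.data[...] = 0.0
        net.attention.b_in.data[...] = 0.0
        mat = extract_attention_weights(net, [rng.normal(size=(67, 20))
                                              for _ in range(3)])
        assert mat.shape == (3, 20)
        np.testing.assert_allclose(mat, 0.5)

    def test_matches_attention_forward_loop(self):
        net = EstimatorNet(seed=1, densenet=TINY_DENSENET, hidden_size=8)
        windows = [rng.normal(size=(67, 20)) for _ in range(4)]
        mat = extract_attention_weights(net, windows)
        assert np.all((mat > 0) & (mat < 1))
        params = AttentionLayerParams(net.attention.w_in.data,
                                      net.attention.b_in.data)
        loop = np.array([attention_forward(w, params).att for w in windows])
        np.testing.assert_allclose(mat, loop, atol=1e-12)
        np.testing.assert_allclose(mat.mean(axis=0), loop.mean(axis=0), atol=1e-12)


def test_small_model_overfits_tiny_fixture():
    """Gradient sanity: training MSE drops below 1e-2 on a 32-window fixture."""
    from insolenet.training import Adam

    net = EstimatorNet(seed=2, densenet=TINY_DENSENET, hidden_size=8)
    r = np.random.default_rng(3)
    x = r.normal(size=(32, 67, 20))
    y = r.normal(size=32)
    opt = Adam(net.parameters(), 3e-3)
    net.set_training(True)
    loss_val = np.inf
    for _ in range(150):
        net.zero_grad()
        pred, _ = net.forward(Tensor(x))
        loss = ((pred - Tensor(y)) ** 2.0).mean()
        loss.backward()
        opt.step()
        loss_val = float(loss.data)
        if loss_val < 1e-2:
            break
    assert loss_val < 1e-2
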