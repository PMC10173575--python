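import numpy as np
import pytest

import renalseg.nn as nn
from renalseg.model import (AttentionGate, DualPathAttentionUNet, NetworkConfig,
                            PlainConvBlock, ResidualConvBlock)
from renalseg.nn import tensor as T


def _zero_block_residual_branches(block: ResidualConvBlock):
    for conv in (block.conv1, block.conv2):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    for bn in (block.bn1, block.bn2):
        bn.identity = True


def _zero_gate(gate: AttentionGate):
    for conv in (gate.theta_x, gate.phi_g, gate.psi):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0


class TestResidualConvBlock:
    def test_zeroed_residual_branches_give_twice_projection(self, rng):
        block = ResidualConvBlock(3, 5, rng)
        _zero_block_residual_branches(block)
        x = rng.normal(size=(2, 3, 8, 8))
        out = block(T.Tensor(x)).data
        proj = T.conv2d(T.Tensor(x), block.proj.weight, block.proj.bias).data
        assert np.allclose(out, 2.0 * proj, atol=1e-12)

    def test_output_shape_contract(self, rng):
        block = ResidualConvBlock(4, 7, rng)
        out = block(T.Tensor(rng.normal(size=(1, 4, 32, 32))))
        assert out.shape == (1, 7, 32, 32)

    def test_matches_stepwise_recomputation(self, rng):
        """Literal re-evaluation of the block algebra outside the container."""
        block = ResidualConvBlock(2, 2, rng)
        for bn in (block.bn1, block.bn2):
            bn.identity = True  # isolate the wiring from batch statistics
        x = rng.normal(size=(1, 2, 6, 6))
        out = block(T.Tensor(x)).data

        def conv(data, layer):
            return T.conv2d(T.Tensor(data), layer.weight, layer.bias,
                            padding=layer.padding).data

        x0 = conv(x, block.proj)
        x1 = np.maximum(conv(x0, block.conv1), 0.0) + x0
        x2 = np.maximum(conv(x1, block.conv2), 0.0) + x1
        assert np.allclose(out, x1 + x2, atol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        block = ResidualConvBlock(3, 4, rng)
        with pytest.raises(ValueError, match="channel mismatch"):
            block(T.Tensor(rng.normal(size=(1, 5, 8, 8))))


class TestAttentionGate:
    def test_zeroed_gate_is_half_multiplier(self, rng):
        gate = AttentionGate(4, 6, rng=rng)
        _zero_gate(gate)
        x_l = rng.normal(size=(2, 4, 8, 8))
        g = rng.normal(size=(2, 6, 4, 4))
        out = gate(T.Tensor(x_l), T.Tensor(g)).data
        assert np.allclose(out, 0.5 * x_l, atol=1e-12)

    def test_alpha_in_open_unit_interval(self, rng):
        gate = AttentionGate(3, 5, rng=rng)
        x_l = rng.normal(size=(1, 3, 8, 8)) * 10
        g = rng.normal(size=(1, 5, 4, 4)) * 10
        alpha = gate.attention_map(x_l, g)
        assert alpha.shape == (1, 1, 8, 8)
        assert np.all(alpha > 0.0) and np.all(alpha < 1.0)

    def test_zero_skip_gives_zero_output(self, rng):
        gate = AttentionGate(3, 5, rng=rng)
        out = gate(T.Tensor(np.zeros((1, 3, 8, 8))),
                   T.Tensor(rng.normal(size=(1, 5, 4, 4)))).data
        assert np.all(out == 0.0)

    def test_extent_mismatch_raises(self, rng):
        gate = AttentionGate(3, 5, rng=rng)
        with pytest.raises(ValueError, match="extent"):
            gate(T.Tensor(np.zeros((1, 3, 8, 8))),
                 T.Tensor(np.zeros((1, 5, 8, 8))))

    def test_equal_extent_config(self, rng):
        gate = AttentionGate(3, 5, rng=rng, gate_factor=1)
        out = gate(T.Tensor(rng.normal(size=(1, 3, 8, 8))),
                   T.Tensor(rng.normal(size=(1, 5, 8, 8))))
        assert out.shape == (1, 3, 8, 8)


class TestNetworkConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(depth=1), dict(base_width=0), dict(num_classes=1),
        dict(block_type="dense"), dict(in_channels=2),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_width_doubles_and_caps(self):
        cfg = NetworkConfig(base_width=64, depth=5)
        assert [cfg.width(i) for i in range(5)] == [64, 128, 256, 512, 512]

    def test_roundtrip_dict(self):
        cfg = NetworkConfig(in_channels=5, num_classes=4, depth=3, base_width=8,
                            block_type="plain", attention=False)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestEncodeDecode:
    def test_encoder_extent_halving_chain(self, rng):
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=3, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        skips, bottleneck = net.encode(T.Tensor(rng.normal(size=(1, 3, 64, 64))))
        assert [s.shape[2] for s in skips] == [64, 32]
        assert bottleneck.shape[2:] == (16, 16)

    def test_channel_bookkeeping(self, rng):
        """Concatenated input of level i = path-1 channels + raw k channels."""
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=4, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        for lvl in range(1, cfg.depth):
            expected_in = cfg.width(lvl - 1) + cfg.in_channels
            assert net.enc_blocks[lvl].proj.in_channels == expected_in
        skips, bottleneck = net.encode(T.Tensor(rng.normal(size=(1, 3, 32, 32))))
        for lvl, s in enumerate(skips):
            assert s.shape[1] == cfg.width(lvl)
        assert bottleneck.shape[1] == cfg.width(cfg.depth - 1)

    def test_indivisible_extent_rejected_before_compute(self, rng):
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=4, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            net.encode(T.Tensor(rng.normal(size=(1, 3, 36, 36))))

    def test_depth2_minimal_topology(self, rng):
        cfg = NetworkConfig(in_channels=1, num_classes=2, depth=2, base_width=2)
        net = DualPathAttentionUNet(cfg, rng=rng)
        out = net(T.Tensor(rng.normal(size=(1, 1, 8, 8))))
        assert out.shape == (1, 2, 8, 8)

    @pytest.mark.parametrize("depth,base_width,k,num_classes,hw", [
        (2, 2, 1, 2, 12), (3, 4, 3, 3, 16), (4, 2, 5, 4, 32),
    ])
    def test_forward_shape_stability(self, depth, base_width, k, num_classes, hw, rng):
        cfg = NetworkConfig(in_channels=k, num_classes=num_classes, depth=depth,
                            base_width=base_width)
        net = DualPathAttentionUNet(cfg, rng=rng)
        out = net(T.Tensor(rng.normal(size=(2, k, hw, hw))))
        assert out.shape == (2, num_classes, hw, hw)

    def test_attention_off_with_zero_gates_is_half_skip(self, rng):
        """With gate weights zeroed, attention-on equals attention-off with the
        skip branch scaled by 0.5 (identical remaining weights)."""
        cfg_on = NetworkConfig(in_channels=3, num_classes=2, depth=2,
                               base_width=4, attention=True)
        cfg_off = NetworkConfig(in_channels=3, num_classes=2, depth=2,
                                base_width=4, attention=False)
        net_on = DualPathAttentionUNet(cfg_on, rng=np.random.default_rng(5))
        net_off = DualPathAttentionUNet(cfg_off, rng=np.random.default_rng(5))
        # align the shared weights (same construction order apart from gates)
        state_on = net_on.state_dict()
        shared = {k: v for k, v in state_on.items() if not k.startswith("gates.")}
        net_off.load_state_dict(shared)
        for gate in net_on.gates:
            _zero_gate(gate)
        # halve the skip contribution in the attention-off net: scale the
        # decoder block's projection columns that see the skip channels
        w = cfg_off.width(0)
        for blk in net_off.dec_blocks:
            proj = blk.proj.weight.data
            proj[:, w:, :, :] *= 0.5  # skip channels are concatenated second
        x = rng.normal(size=(1, 3, 8, 8))
        net_on.eval(); net_off.eval()
        out_on = net_on(T.Tensor(x)).data
        out_off = net_off(T.Tensor(x)).data
        assert np.allclose(out_on, out_off, atol=1e-10)

    def test_decode_config_mismatch_raises(self, rng):
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=3, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        skips, bottleneck = net.encode(T.Tensor(rng.normal(size=(1, 3, 32, 32))))
        with pytest.raises(ValueError, match="skip"):
            net.decode(skips[:1], bottleneck)


class TestTrainingProperties:
    def test_every_parameter_receives_gradient(self, rng):
        cfg = NetworkConfig(in_channels=3, num_classes=3, depth=3, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        x = rng.normal(size=(2, 3, 16, 16))
        y = rng.integers(0, 3, size=(2, 16, 16))
        loss = nn.ce_dice_loss(net(T.Tensor(x)), y)
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None, f"no gradient reached {name}"
            assert np.abs(p.grad).sum() > 0, f"zero gradient at {name}"

    def test_predict_deterministic(self, rng):
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=2, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=rng)
        x = rng.normal(size=(2, 3, 8, 8))
        a = net.predict_batch(x)
        b = net.predict_batch(x.copy())
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1}

    def test_small_overfit(self, rng):
        """A tiny net memorizes one synthetic slice (wiring sanity)."""
        from renalseg.metrics import smoothed_dice
        y = np.zeros((1, 32, 32), dtype=np.int64)
        y[0, 8:20, 10:24] = 1
        x = rng.normal(size=(1, 3, 32, 32)) * 0.1
        x[0, :, 8:20, 10:24] += 2.0
        cfg = NetworkConfig(in_channels=3, num_classes=2, depth=3, base_width=4)
        net = DualPathAttentionUNet(cfg, rng=np.random.default_rng(0))
        opt = nn.Adam(net.parameters(), lr=3e-3)
        losses = []
        for _ in range(120):
            opt.zero_grad()
            loss = nn.ce_dice_loss(net(T.Tensor(x)), y)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]
        pred = net.predict_batch(x)[0]
        assert smoothed_dice(pred > 0, y[0] > 0) >= 0.95
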