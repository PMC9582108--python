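"""Blocks and networks: shape contracts, parameter arithmetic, determinism."""

import numpy as np
import pytest

from dermseg.architectures import (AttentionBlock, FireBlock, FireSpec,
                                   NetworkSpec, TransposedFireBlock,
                                   UpsamplingBlock, build_network,
                                   count_parameters, required_divisor)
from dermseg.metrics import TverskyParams
from dermseg.nn import Conv2d, Module, Tensor, focal_tversky, no_grad


@pytest.fixture
def block_rng():
    return np.random.default_rng(0)


class TestFireBlocks:
    def test_odd_output_channels_rejected(self):
        with pytest.raises(ValueError, match="even"):
            FireSpec(squeeze_channels=16, output_channels=63)
        with pytest.raises(ValueError):
            FireSpec(squeeze_channels=0, output_channels=64)

    def test_fire_shape_propagation(self, block_rng, rng):
        block = FireBlock(64, FireSpec(16, 64), block_rng)
        x = rng.random((1, 64, 12, 16), dtype=np.float32)
        assert block(Tensor(x)).data.shape == (1, 64, 12, 16)

    def test_fire_parameter_count_closed_form(self, block_rng):
        # 1x1 squeeze 64->16: 1040; 3x3 16->32: 4640; 1x1 16->32: 544
        block = FireBlock(64, FireSpec(16, 64), block_rng)
        assert count_parameters(block) == 6224

    def test_transposed_fire_doubles_spatial_size(self, block_rng, rng):
        block = TransposedFireBlock(128, FireSpec(16, 64), block_rng, stride=2)
        x = rng.random((1, 128, 24, 32), dtype=np.float32)
        assert block(Tensor(x)).data.shape == (1, 64, 48, 64)

    def test_transposed_fire_stride1_preserves_size(self, block_rng, rng):
        block = TransposedFireBlock(128, FireSpec(16, 64), block_rng, stride=1)
        x = rng.random((1, 128, 6, 8), dtype=np.float32)
        assert block(Tensor(x)).data.shape == (1, 64, 6, 8)

    def test_transposed_fire_parameter_count_closed_form(self, block_rng):
        # 1x1 transposed 128->16: 2064; 2x2 16->32: 2080; 1x1 16->32: 544
        block = TransposedFireBlock(128, FireSpec(16, 64), block_rng)
        assert count_parameters(block) == 4688


class TestAttentionBlock:
    def test_saturated_gate_is_identity(self, block_rng, rng):
        block = AttentionBlock(8, 8, 4, block_rng)
        block.psi.weight.data[:] = 0.0
        block.psi.bias.data[:] = 100.0          # sigmoid -> 1
        x = rng.random((1, 8, 6, 6), dtype=np.float32)
        g = rng.random((1, 8, 6, 6), dtype=np.float32)
        assert np.allclose(block(Tensor(g), Tensor(x)).data, x)

    def test_closed_gate_zeroes_output(self, block_rng, rng):
        block = AttentionBlock(8, 8, 4, block_rng)
        block.psi.weight.data[:] = 0.0
        block.psi.bias.data[:] = -100.0         # sigmoid -> 0
        x = rng.random((1, 8, 6, 6), dtype=np.float32)
        g = rng.random((1, 8, 6, 6), dtype=np.float32)
        assert np.allclose(block(Tensor(g), Tensor(x)).data, 0.0)

    def test_attention_map_strictly_in_unit_interval(self, block_rng, rng):
        block = AttentionBlock(16, 8, 4, block_rng)
        g = rng.normal(size=(2, 16, 5, 7)).astype(np.float32)
        x = rng.normal(size=(2, 8, 5, 7)).astype(np.float32)
        a = block.attention_map(Tensor(g), Tensor(x)).data
        assert a.shape == (2, 1, 5, 7)
        assert np.all(a > 0.0) and np.all(a < 1.0)

    def test_spatial_mismatch_raises(self, block_rng, rng):
        block = AttentionBlock(8, 8, 4, block_rng)
        g = rng.random((1, 8, 4, 4), dtype=np.float32)
        x = rng.random((1, 8, 8, 8), dtype=np.float32)
        with pytest.raises(ValueError, match="spatial"):
            block(Tensor(g), Tensor(x))


class TestUpsamplingBlock:
    def test_output_matches_skip_resolution(self, block_rng, rng):
        block = UpsamplingBlock(256, 128, 128, block_rng, attention=True)
        g = rng.random((1, 256, 12, 16), dtype=np.float32)
        x = rng.random((1, 128, 24, 32), dtype=np.float32)
        out = block(Tensor(g), Tensor(x))
        assert out.data.shape == (1, 128, 24, 32)

    def test_incompatible_skip_size_raises(self, block_rng, rng):
        block = UpsamplingBlock(256, 128, 128, block_rng, attention=True)
        g = rng.random((1, 256, 12, 16), dtype=np.float32)
        x = rng.random((1, 128, 30, 40), dtype=np.float32)
        with pytest.raises(ValueError, match="twice"):
            block(Tensor(g), Tensor(x))

    def test_parameter_count_is_sum_of_parts(self, block_rng):
        block = UpsamplingBlock(256, 128, 128, block_rng, attention=True)
        parts = (count_parameters(block.up) + count_parameters(block.attention)
                 + count_parameters(block.fuse))
        assert count_parameters(block) == parts


class TestNetworks:
    @pytest.mark.parametrize("arch", ["unet", "attention_unet", "squeeze_unet",
                                      "attention_squeeze_unet"])
    def test_shape_and_softmax_contract(self, arch, rng):
        spec = NetworkSpec(architecture=arch, height=96, width=128, seed=0)
        model = build_network(spec)
        x = rng.random((1, 3, 96, 128), dtype=np.float32)
        with no_grad():
            out = model(Tensor(x)).data
        assert out.shape == (1, 2, 96, 128)
        assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-5

    def test_same_seed_same_weights(self):
        spec = NetworkSpec(architecture="attention_squeeze_unet",
                           height=96, width=128, seed=42)
        a, b = build_network(spec), build_network(spec)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb and np.array_equal(pa.data, pb.data)

    def test_inference_is_deterministic(self, rng):
        model = build_network(NetworkSpec(architecture="squeeze_unet",
                                          height=64, width=64, seed=0))
        x = rng.random((1, 3, 64, 64), dtype=np.float32)
        with no_grad():
            o1 = model(Tensor(x)).data
            o2 = model(Tensor(x)).data
        assert np.array_equal(o1, o2)

    def test_indivisible_input_raises_with_divisor(self):
        with pytest.raises(ValueError, match="32"):
            NetworkSpec(architecture="attention_squeeze_unet", height=96, width=100)
        with pytest.raises(ValueError, match="16"):
            NetworkSpec(architecture="unet", height=100, width=128)
        assert required_divisor("unet") == 16
        assert required_divisor("squeeze_unet") == 32

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            NetworkSpec(architecture="vgg")

    def test_gradient_reaches_every_parameter_group(self, rng):
        model = build_network(NetworkSpec(architecture="attention_squeeze_unet",
                                          height=64, width=64, seed=0))
        x = rng.random((2, 3, 64, 64), dtype=np.float32)
        gt = (rng.random((2, 64, 64)) > 0.8).astype(np.float32)
        loss = focal_tversky(model(Tensor(x)), gt, TverskyParams())
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestParameterCounting:
    def test_single_conv_without_bias(self, block_rng):
        conv = Conv2d(64, 16, 1, block_rng, bias=False)
        assert count_parameters(conv) == 1024

    def test_empty_model(self):
        assert count_parameters(Module()) == 0

    def test_attention_gates_are_the_only_extra_parameters(self):
        squeeze = build_network(NetworkSpec(architecture="squeeze_unet",
                                            height=96, width=128, seed=0))
        attn = build_network(NetworkSpec(architecture="attention_squeeze_unet",
                                         height=96, width=128, seed=0))
        delta = count_parameters(attn) - count_parameters(squeeze)
        gate_params = sum(count_parameters(u.attention) for u in attn.ups)
        assert delta == gate_params > 0
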