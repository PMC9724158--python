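"""Architecture contracts: dilated convolution, fusion, interleaved
upsampling, generator/discriminator/edge-net shape and behaviour."""

import numpy as np
import pytest
from scipy import ndimage

from eggan import autodiff as ad
from eggan.autodiff import Tensor
from eggan.layers import same_padding
from eggan.losses import paired_total
from eggan.nets import (
    DiscriminatorConfig,
    EdgeNetConfig,
    EdgeUNet,
    Generator,
    GeneratorConfig,
    PatchDiscriminator,
    UpsampleBlock,
    dilated_conv,
    g2l_fuse,
    load_checkpoint,
    save_checkpoint,
)

from oracles import dilated_conv_loop


class TestDilatedConv:
    def test_delta_kernel_is_identity(self, rng):
        p = rng.normal(size=(9, 9))
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        for t in (1, 2, 5):
            np.testing.assert_allclose(dilated_conv(p, delta, t).data, p,
                                       atol=1e-12)

    def test_one_dimensional_comb(self):
        p = np.array([[0, 0, 0, 1, 0, 0, 0]], dtype=float)
        k = np.array([[1, 1, 1]], dtype=float)
        out = dilated_conv(p, k, 2)
        np.testing.assert_array_equal(out.data, [[0, 1, 0, 1, 0, 1, 0]])

    @pytest.mark.parametrize("t", [1, 3, 6, 12])
    def test_matches_double_loop_oracle(self, t, rng):
        p = rng.normal(size=(9, 9))
        k = rng.normal(size=(3, 3))
        np.testing.assert_allclose(dilated_conv(p, k, t).data,
                                   dilated_conv_loop(p, k, t), atol=1e-6)

    def test_rate_one_equals_plain_correlation(self, rng):
        p = rng.normal(size=(8, 8))
        k = rng.normal(size=(3, 3))
        ref = ndimage.correlate(p, k, mode="constant", cval=0.0)
        np.testing.assert_allclose(dilated_conv(p, k, 1).data, ref, atol=1e-6)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            dilated_conv(np.zeros((4, 4)), np.zeros((3, 3)), 0)


class TestG2LFuse:
    def test_single_rate_degenerates_to_dilated_conv(self, rng):
        p = rng.normal(size=(8, 8))
        k = rng.normal(size=(3, 3))
        np.testing.assert_allclose(g2l_fuse(p, [k], [3]).data,
                                   dilated_conv(p, k, 3).data, atol=1e-12)

    def test_spatial_size_preserved_for_printed_rates(self, rng):
        p = rng.normal(size=(8, 8))
        kernels = [rng.normal(size=(3, 3)) for _ in range(3)]
        out = g2l_fuse(p, kernels, [3, 6, 12])
        assert out.data.shape == (8, 8)

    def test_sum_mode_additive_identity(self, rng):
        p = rng.normal(size=(8, 8))
        k3 = rng.normal(size=(3, 3))
        zeros = np.zeros((3, 3))
        out = g2l_fuse(p, [k3, zeros, zeros], [3, 6, 12], fusion_mode="sum")
        np.testing.assert_allclose(out.data, dilated_conv(p, k3, 3).data,
                                   atol=1e-12)

    def test_aggregation_order_largest_rate_first(self, rng):
        # with concat_project, the innermost branch is the largest rate:
        # a projection that keeps only its second input must reproduce the
        # fold of the two largest rates, ignoring the rate-3 branch
        p = rng.normal(size=(6, 6))
        kernels = [rng.normal(size=(3, 3)) for _ in range(3)]
        keep_second = np.array([[[[0.0]], [[1.0]]]])  # 1x2x1x1 conv
        out = g2l_fuse(p, kernels, [3, 6, 12], fusion_mode="concat_project",
                       proj_kernels=[keep_second, keep_second])
        expected = dilated_conv(p, kernels[2], 12)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_mismatched_kernel_count_rejected(self, rng):
        with pytest.raises(ValueError):
            g2l_fuse(rng.normal(size=(4, 4)), [np.zeros((3, 3))], [3, 6])


class TestUpsampleBlock:
    def test_doubles_spatial_dims(self, rng):
        block = UpsampleBlock(3, 2, rng)
        out = block(Tensor(rng.normal(size=(1, 3, 8, 8))))
        assert out.shape == (1, 2, 16, 16)

    def test_constant_input_averaging_kernels(self, rng):
        # averaging kernels in branch 1, zeroed branch 2: each phase output
        # equals the (zero-padded) kernel average, so the interior of the
        # upsampled map stays at the input constant
        block = UpsampleBlock(1, 1, rng)
        for conv in block.branch1:
            kh, kw = conv.weight.data.shape[-2:]
            conv.weight.data[:] = 1.0 / (kh * kw)
            conv.bias.data[:] = 0.0
        for conv in block.branch2:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        value = 3.7
        out = block(Tensor(np.full((1, 1, 6, 6), value))).data[0, 0]
        assert out.shape == (12, 12)
        np.testing.assert_allclose(out[2:-4, 2:-4], value, atol=1e-12)

    def test_five_blocks_chain_8_to_256(self, rng):
        blocks = [UpsampleBlock(1, 1, rng) for _ in range(5)]
        x = Tensor(rng.normal(size=(1, 1, 8, 8)))
        for b in blocks:
            x = b(x)
        assert x.shape == (1, 1, 256, 256)

    def test_rectangular_kernels_pad_trailing_edge(self):
        assert same_padding(2, 2) == (0, 1, 0, 1)
        assert same_padding(3, 2) == (1, 1, 0, 1)
        assert same_padding(2, 3) == (0, 1, 1, 1)


class TestGeneratorContracts:
    @pytest.mark.parametrize("size,levels", [(64, 3), (128, 4), (256, 5)])
    def test_output_shape_matches_input(self, size, levels, rng):
        cfg = GeneratorConfig(input_size=size, levels=levels, base_channels=2,
                              res_blocks_per_level=1, dilation_rates=(2, 4))
        gen = Generator(cfg, rng)
        out = gen.translate(rng.normal(size=(size, size)))
        assert out.shape == (size, size)

    def test_default_config_bottleneck_is_8(self):
        assert GeneratorConfig().bottleneck_size == 8

    def test_forward_is_deterministic(self, rng):
        cfg = GeneratorConfig(input_size=32, levels=2, base_channels=2,
                              res_blocks_per_level=1, dilation_rates=(2,))
        gen = Generator(cfg, rng)
        x = rng.normal(size=(32, 32))
        np.testing.assert_array_equal(gen.translate(x), gen.translate(x))

    def test_wrong_input_size_raises(self, rng):
        cfg = GeneratorConfig(input_size=32, levels=2, base_channels=2,
                              res_blocks_per_level=1, dilation_rates=(2,))
        gen = Generator(cfg, rng)
        with pytest.raises(ValueError, match="config expects"):
            gen.forward(Tensor(np.zeros((1, 1, 64, 64))))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(input_size=100, levels=5)
        with pytest.raises(ValueError):
            GeneratorConfig(input_size=64, levels=5)  # bottleneck 2 < 4
        with pytest.raises(ValueError):
            GeneratorConfig(dilation_rates=(6, 3))
        with pytest.raises(ValueError):
            GeneratorConfig(fusion_mode="mystery")

    def test_gradients_flow_to_every_parameter(self, rng):
        cfg = GeneratorConfig(input_size=16, levels=2, base_channels=2,
                              res_blocks_per_level=1, dilation_rates=(2, 4))
        gen = Generator(cfg, rng)
        x = Tensor(rng.normal(size=(1, 1, 16, 16)))
        y = Tensor(rng.normal(size=(1, 1, 16, 16)))
        e_t, _ = paired_total(gen.forward(x), y)
        e_t.backward()
        for p in gen.parameters():
            assert p.grad is not None and np.isfinite(p.grad).all()


class TestDiscriminator:
    def test_score_grid_shape_at_256(self, rng):
        disc = PatchDiscriminator(DiscriminatorConfig(n_layers=3,
                                                      base_channels=4), rng)
        with ad.no_grad():
            scores = disc(Tensor(rng.normal(size=(1, 1, 256, 256))))
        # 256 -> 128 -> 64 -> 32 (stride 2), then two stride-1 4x4 convs
        assert scores.shape == (1, 1, 30, 30)

    def test_patch_locality_shift_equivariance(self, rng):
        # 2-layer stack: each score covers a 34-px patch, so on a 128-px
        # image interior scores depend only on their patch; a 4-px (one
        # score cell) circular shift moves the interior scores by one cell
        disc = PatchDiscriminator(DiscriminatorConfig(n_layers=2,
                                                      base_channels=4), rng)
        # zero band wider than the receptive field isolates the pattern from
        # the zero-padding border, making the shift exact everywhere
        x = np.zeros((1, 1, 128, 128))
        x[..., 40:-44] = rng.normal(size=(1, 1, 128, 44))
        shift = 4
        x_shifted = np.roll(x, shift, axis=3)
        with ad.no_grad():
            s = disc(Tensor(x)).data[0, 0]
            s2 = disc(Tensor(x_shifted)).data[0, 0]
        margin = 10
        np.testing.assert_allclose(s2[:, margin + 1:-margin],
                                   s[:, margin:-margin - 1], atol=1e-8)

    def test_zero_weights_zero_scores(self, rng):
        disc = PatchDiscriminator(DiscriminatorConfig(n_layers=2,
                                                      base_channels=2), rng)
        for t in disc.all_tensors():
            t.data[:] = 0.0
        with ad.no_grad():
            scores = disc(Tensor(rng.normal(size=(1, 1, 32, 32))))
        np.testing.assert_array_equal(scores.data, 0.0)


class TestEdgeNet:
    def test_output_range_and_shape(self, rng):
        net = EdgeUNet(EdgeNetConfig(depth=3, base_channels=2), rng)
        out = net.edge_map_array(rng.normal(size=(32, 32)))
        assert out.shape == (32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_freeze_marks_all_parameters(self, rng):
        net = EdgeUNet(EdgeNetConfig(depth=2, base_channels=2), rng)
        assert len(net.parameters()) > 0
        net.freeze()
        assert len(net.parameters()) == 0

    def test_indivisible_input_rejected(self, rng):
        net = EdgeUNet(EdgeNetConfig(depth=4, base_channels=2), rng)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(Tensor(np.zeros((1, 1, 20, 20))))


class TestCheckpoints:
    def test_generator_roundtrip(self, tmp_path, rng):
        cfg = GeneratorConfig(input_size=32, levels=2, base_channels=2,
                              res_blocks_per_level=1, dilation_rates=(2,))
        gen = Generator(cfg, rng)
        x = rng.normal(size=(32, 32))
        before = gen.translate(x)
        path = tmp_path / "gen.npz"
        save_checkpoint(path, "generator", cfg, gen)
        kind, cfg2, gen2 = load_checkpoint(path)
        assert kind == "generator" and cfg2 == cfg
        np.testing.assert_array_equal(gen2.translate(x), before)

    def test_frozen_load(self, tmp_path, rng):
        cfg = EdgeNetConfig(depth=2, base_channels=2)
        net = EdgeUNet(cfg, rng)
        path = tmp_path / "edge.npz"
        save_checkpoint(path, "edge_net", cfg, net)
        _, _, net2 = load_checkpoint(path, frozen=True)
        assert len(net2.parameters()) == 0
        x = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(net2.edge_map_array(x),
                                      net.edge_map_array(x))

    def test_unknown_kind_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError, match="unknown"):
            save_checkpoint(tmp_path / "x.npz", "mystery",
                            EdgeNetConfig(), EdgeUNet(EdgeNetConfig(2, 2), rng))
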