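"""Prior network: encoder, context blocks, ROI localization, attention."""

import numpy as np
import pytest

from cgad.autodiff import Tensor
from cgad.prior_model import (
    HPCM,
    IDCR,
    ChannelAttention,
    Encoder,
    PriorConfig,
    PriorModel,
    locate_roi,
)


def _rng():
    return np.random.default_rng(7)


def _positivize(module):
    """Make all conv weights positive so relu never gates a gradient probe."""
    for _, p in module.named_parameters():
        p.data[...] = np.abs(p.data) + 0.01


def _input_footprint(module, channels: int, size: int) -> tuple[int, int]:
    """Bounding box of nonzero input gradient from one centred output unit."""
    x = Tensor(np.ones((1, channels, size, size)), requires_grad=True)
    out = module(x)
    mid = size // 2
    pick = out * Tensor(_one_pixel_mask(out.shape, mid))
    pick.sum().backward()
    rows, cols = np.nonzero(np.abs(x.grad).sum(axis=(0, 1)))
    return rows.max() - rows.min() + 1, cols.max() - cols.min() + 1


def _one_pixel_mask(shape, mid):
    m = np.zeros(shape)
    m[:, :, mid, mid] = 1.0
    return m


class TestEncoder:
    def test_stride_eight_shape_contract(self):
        enc = Encoder(4, _rng())
        out = enc(Tensor(np.zeros((2, 3, 64, 64))))
        assert out.shape == (2, enc.out_channels, 8, 8)

    def test_rejects_too_small_input(self):
        enc = Encoder(4, _rng())
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 3, 16, 16))))

    def test_zero_image_gives_zero_features(self):
        enc = Encoder(4, _rng())  # biases are zero-initialized
        out = enc(Tensor(np.zeros((1, 3, 32, 32))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_first_stage_preactivation_is_linear_in_contrast(self):
        from cgad.autodiff import conv2d

        enc = Encoder(4, _rng())
        x = np.random.default_rng(0).standard_normal((1, 3, 32, 32))
        a = conv2d(Tensor(x), enc.stem.w, enc.stem.b).data
        b = conv2d(Tensor(2 * x), enc.stem.w, enc.stem.b).data
        np.testing.assert_allclose(b, 2 * a, atol=1e-12)


class TestContextBlocks:
    @pytest.mark.parametrize("hw", [(8, 8), (12, 20)])
    def test_hpcm_preserves_spatial_dimensions(self, hw):
        block = HPCM(6, _rng())
        out = block(Tensor(np.random.default_rng(1).standard_normal((2, 6, *hw))))
        assert out.shape[-2:] == hw

    @pytest.mark.parametrize("hw", [(8, 8), (9, 15)])
    def test_idcr_preserves_spatial_dimensions(self, hw):
        block = IDCR(6, _rng())
        out = block(Tensor(np.random.default_rng(1).standard_normal((2, 6, *hw))))
        assert out.shape[-2:] == hw

    def test_hpcm_zero_weights_zero_input_give_zero(self):
        block = HPCM(4, _rng())
        out = block(Tensor(np.zeros((1, 4, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_idcr_residual_identity_with_zero_stack(self):
        block = IDCR(4, _rng())
        for _, p in block.named_parameters():
            p.data[...] = 0.0
        x = np.random.default_rng(2).standard_normal((1, 4, 8, 8))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    def test_dilated_branch_receptive_field_is_17(self):
        """A single 3x3 convolution at rate 8 sees 1 + 2*8 = 17 pixels."""
        block = HPCM(2, _rng(), rates=(2, 4, 8))
        rate8 = block.dilated[-1]
        _positivize(rate8)
        assert _input_footprint(rate8, 2, 41) == (17, 17)

    def test_idcr_stack_receptive_field_is_15(self):
        """Stacked 3x3 convolutions at rates (1, 2, 4): 1 + 2*(1+2+4) = 15.
        Probed through the stack alone (the residual path would add a
        direct 1x1 connection)."""
        block = IDCR(2, _rng(), rates=(1, 2, 4))
        _positivize(block)

        class StackOnly:
            def __call__(self, x):
                h = x
                for i, conv in enumerate(block.stack):
                    h = conv(h)
                    if i < len(block.stack) - 1:
                        h = h.relu()
                return h

        assert _input_footprint(StackOnly(), 2, 31) == (15, 15)

    def test_hpcm_widens_receptive_field_beyond_standard_conv(self):
        block = HPCM(2, _rng(), rates=(2, 4, 8))
        _positivize(block)
        std = _input_footprint(block.standard, 2, 41)
        full = _input_footprint(block, 2, 41)
        assert full[0] > std[0] and full[1] > std[1]


class TestChannelAttention:
    def test_zero_initialized_gates_are_half(self):
        att = ChannelAttention(8, _rng())
        for _, p in att.named_parameters():
            p.data[...] = 0.0
        g = att.gates(Tensor(np.random.default_rng(3).standard_normal((2, 8, 4, 4))))
        np.testing.assert_allclose(g.data, 0.5)

    def test_gates_bounded_in_unit_interval(self):
        att = ChannelAttention(8, _rng())
        g = att.gates(Tensor(100.0 * np.random.default_rng(3).standard_normal((2, 8, 4, 4))))
        assert np.all((g.data > 0) & (g.data < 1))

    def test_squeeze_statistic_linear_in_channel_scale(self):
        att = ChannelAttention(4, _rng())
        f = np.abs(np.random.default_rng(4).standard_normal((1, 4, 4, 4)))
        f2 = f.copy()
        f2[:, 1] *= 3.0
        s1 = Tensor(f).mean(axis=(2, 3)).data
        s2 = Tensor(f2).mean(axis=(2, 3)).data
        assert s2[0, 1] == pytest.approx(3.0 * s1[0, 1])
        assert s2[0, 0] == pytest.approx(s1[0, 0])


class TestLocateROI:
    def test_centered_peak_gives_centered_box(self):
        yy, xx = np.mgrid[0:16, 0:16]
        resp = np.exp(-((yy - 7.5) ** 2 + (xx - 7.5) ** 2) / 8.0)  # symmetric bump
        r0, r1, c0, c1 = locate_roi(resp, (6, 6))
        assert (r0 + r1) / 2 == pytest.approx(8.0, abs=0.6)
        assert (c0 + c1) / 2 == pytest.approx(8.0, abs=0.6)

    def test_uniform_map_tie_breaks_to_top_left(self):
        box = locate_roi(np.ones((12, 12)), (5, 4))
        assert box == (0, 5, 0, 4)

    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            resp = rng.standard_normal((16, 16))
            r0, r1, c0, c1 = locate_roi(resp, (5, 5))
            best, best_box = -np.inf, None
            for i in range(12):
                for j in range(12):
                    s = resp[i : i + 5, j : j + 5].sum()
                    if s > best + 1e-12:
                        best, best_box = s, (i, i + 5, j, j + 5)
            assert (r0, r1, c0, c1) == best_box

    def test_upsampling_to_image_coordinates(self):
        resp = np.zeros((4, 4))
        resp[3, 3] = 1.0
        r0, r1, c0, c1 = locate_roi(resp, (8, 8), image_size=(32, 32))
        assert 0 <= r0 and r1 <= 32 and r1 - r0 == 8 and c1 - c0 == 8
        assert r0 > 10 and c0 > 10  # bottom-right quadrant

    def test_crop_larger_than_map_rejected(self):
        with pytest.raises(ValueError):
            locate_roi(np.zeros((8, 8)), (9, 9))


class TestPriorModel:
    @pytest.fixture(scope="class")
    def model(self):
        cfg = PriorConfig(n_classes=3, base_channels=4, latent_dim=8)
        return PriorModel(cfg, np.random.default_rng(5))

    @pytest.fixture(scope="class")
    def images(self):
        return np.random.default_rng(6).standard_normal((2, 3, 64, 64))

    def test_bundle_shapes(self, model, images):
        b = model(images)
        assert b.y_g.shape == (2, 3)
        assert b.y_l.shape == (2, 3)
        assert b.y_f.shape == (2, 3)
        assert b.rho_x.shape == (2, 8)
        assert b.aux_logits.shape == (2, 3)
        for r0, r1, c0, c1 in b.roi_boxes:
            assert 0 <= r0 < r1 <= 64 and 0 <= c0 < c1 <= 64
            assert (r1 - r0, c1 - c0) == (32, 32)

    def test_outputs_finite_and_deterministic(self, model, images):
        a, b = model(images), model(images)
        for field in ("y_g", "y_l", "y_f", "rho_x"):
            va, vb = getattr(a, field).data, getattr(b, field).data
            assert np.all(np.isfinite(va))
            np.testing.assert_array_equal(va, vb)

    def test_per_image_bundle_independent_of_batch_order(self, model, images):
        fwd = model(images)
        rev = model(images[::-1])
        np.testing.assert_allclose(fwd.y_g.data[0], rev.y_g.data[1], atol=1e-10)
        np.testing.assert_allclose(fwd.y_l.data[1], rev.y_l.data[0], atol=1e-10)

    def test_fuse_rejects_spatial_mismatch(self, model):
        a = Tensor(np.zeros((1, model.encoder.out_channels, 8, 8)))
        b = Tensor(np.zeros((1, model.encoder.out_channels, 4, 4)))
        with pytest.raises(ValueError):
            model.fuse_global(a, b)

    def test_fuse_concatenates_channels(self, model):
        C = model.encoder.out_channels
        a = Tensor(np.zeros((1, C, 8, 8)))
        _, g_feat, resp = model.fuse_global(a, a)
        assert g_feat.shape == (1, 2 * C)
        assert resp.shape == (1, 1, 8, 8)

    def test_disabled_context_blocks_fall_back_to_identity(self):
        cfg = PriorConfig(n_classes=2, base_channels=4, latent_dim=8,
                          use_hpcm=False, use_idcr=False)
        model = PriorModel(cfg, np.random.default_rng(8))
        imgs = np.random.default_rng(9).standard_normal((1, 3, 64, 64))
        b = model(imgs)
        assert b.y_g.shape == (1, 2)
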