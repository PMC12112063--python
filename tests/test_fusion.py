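"""Content-guided attention and mixup fusion."""
import numpy as np
import pytest
from scipy.special import expit

from uwseg.fusion import (CGA, CGAConfig, CGAFusion, ChannelAttention,
                          SpatialAttention, channel_shuffle, compute_sim,
                          mixup_fuse)
from uwseg.nn import Tensor, no_grad
from uwseg.nn import functional as F


class TestChannelAttention:
    def test_bottleneck_width(self, rng):
        ca = ChannelAttention(16, 8, rng=rng)
        assert ca.fc1.weight.shape == (2, 16, 1, 1)
        assert ca.fc2.weight.shape == (16, 2, 1, 1)

    def test_zero_input_zero_bias_gives_zero(self, rng):
        ca = ChannelAttention(16, 8, rng=rng)
        ca.fc1.bias.data[...] = 0
        ca.fc2.bias.data[...] = 0
        with no_grad():
            w = ca(Tensor(np.zeros((1, 16, 4, 4), np.float32))).data
        np.testing.assert_allclose(w, 0, atol=1e-7)

    def test_spatial_shuffle_invariance(self, rng):
        ca = ChannelAttention(16, 8, rng=rng)
        x = rng.normal(0, 1, (1, 16, 4, 4)).astype(np.float32)
        perm = rng.permutation(16)  # permute pixels within each channel
        xs = x.reshape(1, 16, -1)[:, :, perm].reshape(x.shape)
        with no_grad():
            np.testing.assert_allclose(ca(Tensor(x)).data, ca(Tensor(xs)).data,
                                       atol=1e-6)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ChannelAttention(4, 8, rng=rng)


class TestSpatialAttention:
    def test_output_shape_any_channel_count(self, rng):
        sa = SpatialAttention(rng=rng)
        for c in (3, 16):
            with no_grad():
                w = sa(Tensor(rng.normal(0, 1, (2, c, 5, 6)).astype(np.float32)))
            assert w.shape == (2, 1, 5, 6)

    def test_mean_max_maps_match_loop(self, rng):
        x = rng.normal(0, 1, (1, 4, 3, 3)).astype(np.float32)
        mean_map = Tensor(x).mean(axis=1, keepdims=True).data
        max_map = Tensor(x).max(axis=1, keepdims=True).data
        for i in range(3):
            for j in range(3):
                assert mean_map[0, 0, i, j] == pytest.approx(x[0, :, i, j].mean(), abs=1e-6)
                assert max_map[0, 0, i, j] == pytest.approx(x[0, :, i, j].max(), abs=1e-6)

    def test_constant_input_constant_interior(self, rng):
        sa = SpatialAttention(rng=rng)
        with no_grad():
            w = sa(Tensor(np.full((1, 3, 12, 12), 2.0, np.float32))).data
        interior = w[0, 0, 3:-3, 3:-3]
        assert np.ptp(interior) < 1e-5


class TestChannelShuffle:
    def test_c4_g2_order(self):
        x = np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1)
        y = channel_shuffle(Tensor(x), 2).data.reshape(-1)
        np.testing.assert_array_equal(y, [0, 2, 1, 3])

    def test_inverse_shuffle_restores(self, rng):
        x = rng.normal(0, 1, (2, 12, 3, 3)).astype(np.float32)
        y = channel_shuffle(channel_shuffle(Tensor(x), 3), 4).data
        np.testing.assert_array_equal(y, x)

    def test_preserves_channel_multiset(self, rng):
        x = rng.normal(0, 1, (1, 6, 2, 2)).astype(np.float32)
        y = channel_shuffle(Tensor(x), 2).data
        a = {x[0, c].tobytes() for c in range(6)}
        b = {y[0, c].tobytes() for c in range(6)}
        assert a == b

    def test_indivisible_raises(self):
        with pytest.raises(ValueError):
            channel_shuffle(Tensor(np.zeros((1, 5, 2, 2), np.float32)), 2)


def cga_reference(x, cga):
    """Straight-line re-implementation without shuffling tricks."""
    gap = x.mean(axis=(2, 3), keepdims=True)
    h1 = np.maximum(
        np.einsum("oc,ncij->noij", cga.channel_attn.fc1.weight.data[:, :, 0, 0], gap)
        + cga.channel_attn.fc1.bias.data.reshape(1, -1, 1, 1), 0)
    wc = (np.einsum("oc,ncij->noij", cga.channel_attn.fc2.weight.data[:, :, 0, 0], h1)
          + cga.channel_attn.fc2.bias.data.reshape(1, -1, 1, 1))
    stacked = np.stack([x.mean(axis=1), x.max(axis=1)], axis=1)
    wk = cga.spatial_attn.conv.weight.data
    n, _, hh, ww = x.shape
    pad = np.pad(stacked, ((0, 0), (0, 0), (3, 3), (3, 3)))
    ws = np.zeros((n, 1, hh, ww), np.float32)
    for i in range(hh):
        for j in range(ww):
            ws[:, 0, i, j] = (pad[:, :, i:i + 7, j:j + 7] * wk[0]).sum(axis=(1, 2, 3))
    ws += cga.spatial_attn.conv.bias.data
    w_cos = wc + ws                                     # broadcast C x H x W
    c = x.shape[1]
    cat = np.concatenate([x, np.broadcast_to(w_cos, x.shape)], axis=1)
    g = 2                                                # shuffle groups
    shuffled = cat.reshape(n, g, c, hh, ww).transpose(0, 2, 1, 3, 4).reshape(n, 2 * c, hh, ww)
    gw = cga.group_conv.weight.data                      # (c, 2, 7, 7)
    padg = np.pad(shuffled, ((0, 0), (0, 0), (3, 3), (3, 3)))
    out = np.zeros((n, c, hh, ww), np.float32)
    for o in range(c):
        for i in range(hh):
            for j in range(ww):
                patch = padg[:, 2 * o:2 * o + 2, i:i + 7, j:j + 7]
                out[:, o, i, j] = (patch * gw[o]).sum(axis=(1, 2, 3))
    out += cga.group_conv.bias.data.reshape(1, -1, 1, 1)
    return expit(out)


class TestComputeSim:
    def test_sim_in_open_unit_interval_with_full_shape(self, rng):
        x = rng.normal(0, 1, (2, 16, 6, 6)).astype(np.float32)
        w = compute_sim(x, CGAConfig(), rng=rng).data
        assert w.shape == x.shape
        assert (w > 0).all() and (w < 1).all()

    def test_wcos_broadcast_shape(self, rng):
        cga = CGA(16, rng=rng)
        x = Tensor(rng.normal(0, 1, (1, 16, 5, 5)).astype(np.float32))
        with no_grad():
            wc = cga.channel_attn(x)
            ws = cga.spatial_attn(x)
        assert wc.shape == (1, 16, 1, 1) and ws.shape == (1, 1, 5, 5)
        assert (wc + ws).shape == (1, 16, 5, 5)

    def test_matches_straight_line_reference(self, rng):
        cga = CGA(8, CGAConfig(reduction_ratio=4), rng=rng)
        x = rng.normal(0, 1, (2, 8, 6, 6)).astype(np.float32)
        with no_grad():
            w = cga(Tensor(x)).data
        np.testing.assert_allclose(w, cga_reference(x, cga), atol=1e-5)

    def test_deterministic(self, rng):
        cga = CGA(8, CGAConfig(reduction_ratio=4), rng=rng)
        x = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
        with no_grad():
            np.testing.assert_array_equal(cga(x).data, cga(x).data)


class TestMixupFusion:
    def test_forced_half_weight_averages_streams(self, rng):
        fuser = CGAFusion(8, CGAConfig(reduction_ratio=4), rng=rng)
        fuser.eval()
        low = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
        high = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
        half = Tensor(np.full((1, 8, 4, 4), 0.5, np.float32))
        with no_grad():
            forced = fuser(low, high, weight_override=half).data
            avg = fuser.out_bn(fuser.out_conv((low + high) * 0.5)).data
        np.testing.assert_allclose(forced, avg, atol=1e-6)

    def test_equal_streams_ignore_weights(self, rng):
        fuser = CGAFusion(8, CGAConfig(reduction_ratio=4), rng=rng)
        fuser.eval()
        x = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
        with no_grad():
            fused = fuser(x, x).data
            direct = fuser.out_bn(fuser.out_conv(x)).data
        np.testing.assert_allclose(fused, direct, atol=1e-6)

    def test_premix_is_convex_combination(self, rng):
        fuser = CGAFusion(8, CGAConfig(reduction_ratio=4), rng=rng)
        low = Tensor(rng.normal(0, 1, (1, 8, 5, 5)).astype(np.float32))
        high = Tensor(rng.normal(0, 1, (1, 8, 5, 5)).astype(np.float32))
        with no_grad():
            w = fuser.cga(low + high).data
        mixed = low.data * w + high.data * (1 - w)
        lo = np.minimum(low.data, high.data)
        hi = np.maximum(low.data, high.data)
        assert (mixed >= lo - 1e-6).all() and (mixed <= hi + 1e-6).all()

    def test_parameter_count_independent_of_input_size(self, rng):
        fuser = CGAFusion(16, rng=rng)
        n0 = fuser.num_parameters()
        for size in (4, 16):
            with no_grad():
                fuser(Tensor(np.zeros((1, 16, size, size), np.float32)),
                      Tensor(np.zeros((1, 16, size, size), np.float32)))
        assert fuser.num_parameters() == n0

    def test_shape_mismatch_rejected(self, rng):
        fuser = CGAFusion(8, CGAConfig(reduction_ratio=4), rng=rng)
        with pytest.raises(ValueError, match="fusion streams"):
            fuser(Tensor(np.zeros((1, 8, 4, 4), np.float32)),
                  Tensor(np.zeros((1, 8, 8, 8), np.float32)))

    def test_functional_entry_point(self, rng):
        out = mixup_fuse(np.zeros((1, 8, 4, 4), np.float32),
                         np.zeros((1, 8, 4, 4), np.float32),
                         CGAConfig(reduction_ratio=4), rng=rng)
        assert out.shape == (1, 8, 4, 4)
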