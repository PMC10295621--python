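"""Contracts and closed-form counts of the LDA-A / LDA-B / LMLP blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lcmunet.tensor as T
from lcmunet.blocks import (AsymmetricConvPair, DepthwiseSeparableConv,
                            LDABlock, LdaConfig, LMLPBlock, LmlpConfig,
                            SqueezeExcite, default_se_reduction)
from lcmunet.nn import BatchNorm2d
from lcmunet.objectives import dice_bce_loss
from lcmunet.tensor import Tensor

import oracles


def _rng(seed=0):
    return np.random.default_rng(seed)


def _x(shape, seed=0):
    return Tensor(_rng(seed).standard_normal(shape).astype(np.float32))


def _disable_bn(module):
    """Make every BatchNorm an identity (unit scale, zero shift, frozen stats)."""
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            m.weight.data[:] = np.sqrt(1.0 + m.eps)
            m.bias.data[:] = 0.0
            m.running_mean[:] = 0.0
            m.running_var[:] = 1.0
    module.eval()


# ---------------------------------------------------------------------------
# depthwise-separable convolution
# ---------------------------------------------------------------------------

def test_dwsep_shape_and_param_count():
    blk = DepthwiseSeparableConv(16, 32, rng=_rng())
    out = blk(_x((1, 16, 32, 32)))
    assert out.shape == (1, 32, 32, 32)
    n_conv = sum(p.data.size for name, p in blk.named_parameters()
                 if "bn" not in name)
    assert n_conv == 9 * 16 + 16 * 32 == 656
    assert blk.num_parameters() == oracles.dwsep_params(16, 32)


def test_dwsep_zero_weights_give_zero_output_pre_bn():
    blk = DepthwiseSeparableConv(4, 8, rng=_rng())
    blk.depthwise.weight.data[:] = 0.0
    _disable_bn(blk)
    out = blk(_x((2, 4, 8, 8)))
    assert np.allclose(out.data, 0.0)


def test_dwsep_rejects_wrong_channel_count():
    blk = DepthwiseSeparableConv(4, 8, rng=_rng())
    with pytest.raises(ValueError, match="channels"):
        blk(_x((1, 5, 8, 8)))


# ---------------------------------------------------------------------------
# asymmetric convolution pair
# ---------------------------------------------------------------------------

def test_asym_pair_shape_and_full_param_count():
    blk = AsymmetricConvPair(32, rng=_rng())
    out = blk(_x((1, 32, 16, 16)))
    assert out.shape == (1, 32, 16, 16)
    n_conv = blk.conv_1xk.weight.data.size + blk.conv_kx1.weight.data.size
    assert n_conv == 3 * 32 * 32 + 3 * 32 * 32 == 6144
    assert blk.num_parameters() == oracles.asym_pair_params(32)


def test_asym_pair_depthwise_param_count():
    blk = AsymmetricConvPair(32, kernel=5, depthwise=True, rng=_rng())
    assert blk.num_parameters() == oracles.asym_pair_params(32, 5, depthwise=True)


def test_asym_pair_delta_kernel_is_identity():
    blk = AsymmetricConvPair(3, depthwise=True, batch_norm=False, rng=_rng())
    blk.conv_1xk.weight.data[:] = np.array([0.0, 1.0, 0.0]).reshape(1, 1, 3)
    blk.conv_kx1.weight.data[:] = np.array([0.0, 1.0, 0.0]).reshape(1, 3, 1)
    x = _x((2, 3, 7, 7))
    assert np.allclose(blk(x).data, x.data, atol=1e-6)


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------

def test_se_squeeze_of_constant_channels_is_exact():
    se = SqueezeExcite(4, 2, rng=_rng())
    c = np.arange(1.0, 5.0, dtype=np.float32)
    x = Tensor(np.broadcast_to(c[None, :, None, None], (2, 4, 6, 6)).copy())
    z = se.squeeze(x)
    assert np.allclose(z.data, np.stack([c, c]), atol=1e-6)


def test_se_output_bounded_by_input_for_arbitrary_weights():
    rng = _rng(5)
    se = SqueezeExcite(8, 4, rng=rng)
    for p in se.parameters():           # exaggerate the weights
        p.data *= 50.0
    x = _x((3, 8, 5, 5), seed=6)
    out = se(x)
    assert np.all(np.abs(out.data) <= np.abs(x.data) + 1e-6)


def test_se_param_count_closed_form():
    se = SqueezeExcite(32, 4, rng=_rng())
    assert se.num_parameters() == 32 * 8 + 8 + 8 * 32 + 32 == 552
    assert se.num_parameters() == oracles.se_params(32, 4)


def test_se_rejects_nondividing_reduction():
    with pytest.raises(ValueError, match="divisible"):
        SqueezeExcite(10, 4, rng=_rng())
    with pytest.raises(ValueError, match="divisible"):
        LdaConfig(8, 10, use_se=True, se_reduction=4)


# ---------------------------------------------------------------------------
# LDA blocks
# ---------------------------------------------------------------------------

def test_lda_a_table_row_shape():
    blk = LDABlock(LdaConfig(3, 16, stride=2), rng=_rng())
    out = blk(_x((1, 3, 256, 256)))
    assert out.shape == (1, 16, 128, 128)


def test_lda_b_table_row_shape():
    blk = LDABlock(LdaConfig(16, 32, stride=2, use_se=True, se_reduction=4),
                   rng=_rng())
    out = blk(_x((1, 16, 128, 128)))
    assert out.shape == (1, 32, 64, 64)


@settings(max_examples=15, deadline=None)
@given(a=st.integers(1, 8), b=st.integers(1, 8),
       hw=st.sampled_from([8, 12, 16]), stride=st.sampled_from([1, 2]))
def test_lda_shape_conservation_property(a, b, hw, stride):
    blk = LDABlock(LdaConfig(a, b, stride=stride), rng=_rng(a * 8 + b))
    out = blk(_x((2, a, hw, hw), seed=hw))
    assert out.shape == (2, b, hw // stride, hw // stride)


def test_lda_fusion_is_add_not_concat():
    # output width equals the configured channels, never a sum of addends
    blk = LDABlock(LdaConfig(8, 12), rng=_rng())
    out = blk(_x((1, 8, 16, 16)))
    assert out.shape[1] == 12


def test_lda_rejects_channel_mismatch():
    blk = LDABlock(LdaConfig(8, 12), rng=_rng())
    with pytest.raises(ValueError, match="channels"):
        blk(_x((1, 9, 16, 16)))


def test_lda_zero_main_path_reduces_to_input_projection():
    blk = LDABlock(LdaConfig(4, 6), rng=_rng())
    for conv in (blk.conv1, blk.dwconv, blk.conv2, blk.asym.conv_1xk,
                 blk.asym.conv_kx1, blk.shortcut2):
        conv.weight.data[:] = 0.0
    _disable_bn(blk)
    x = _x((2, 4, 8, 8))
    out = blk(x)
    proj = blk.shortcut(x)
    assert np.allclose(out.data, np.maximum(proj.data, 0.0), atol=1e-5)


@pytest.mark.parametrize("a,b", [(3, 16), (16, 32), (128, 32), (160, 256)])
def test_lda_param_counts_match_closed_form(a, b):
    blk_a = LDABlock(LdaConfig(a, b), rng=_rng())
    assert blk_a.num_parameters() == oracles.lda_params(a, b)
    r = default_se_reduction(b)
    blk_b = LDABlock(LdaConfig(a, b, use_se=True), rng=_rng())
    assert blk_b.num_parameters() == oracles.lda_params(a, b, use_se=True)
    # LDA-B minus LDA-A equals the SE closed form at the output width
    assert blk_b.num_parameters() - blk_a.num_parameters() == \
        oracles.se_params(b, r)


def test_lda_b_with_saturated_se_equals_lda_a():
    rng_a, rng_b = _rng(3), _rng(3)
    blk_a = LDABlock(LdaConfig(4, 8), rng=rng_a)
    blk_b = LDABlock(LdaConfig(4, 8, use_se=True, se_reduction=2), rng=rng_b)
    # copy the shared weights, then saturate the excitation at S = 1
    shared = blk_a.state_dict()
    blk_b.load_state_dict({k: shared.get(k, v)
                           for k, v in blk_b.state_dict().items()})
    blk_b.se.fc2.weight.data[:] = 0.0
    blk_b.se.fc2.bias.data[:] = 100.0     # sigmoid(100) == 1
    blk_a.eval()
    blk_b.eval()
    x = _x((2, 4, 8, 8))
    assert np.allclose(blk_a(x).data, blk_b(x).data, atol=1e-5)


# ---------------------------------------------------------------------------
# LMLP block
# ---------------------------------------------------------------------------

def test_lmlp_preserves_shape():
    blk = LMLPBlock(LmlpConfig(160), rng=_rng())
    out = blk(_x((1, 160, 16, 16)))
    assert out.shape == (1, 160, 16, 16)


def test_lmlp_zero_shift_is_identity_permutation():
    from lcmunet.blocks import _shift_offsets
    offsets = _shift_offsets(10, 0)
    assert np.all(offsets == 0)
    x = _x((1, 10, 6, 6))
    shifted = T.axial_shift(x, offsets, axis=3)
    assert np.allclose(shifted.data, x.data)


def test_lmlp_param_count_closed_form():
    for c in (128, 160, 256):
        blk = LMLPBlock(LmlpConfig(c), rng=_rng())
        assert blk.num_parameters() == oracles.lmlp_params(c)


def test_lmlp_add_flags_change_values_not_shapes():
    x = _x((1, 20, 8, 8))
    outs = {}
    for add1 in (False, True):
        for add2 in (False, True):
            blk = LMLPBlock(LmlpConfig(20, enable_add1=add1, enable_add2=add2),
                            rng=_rng(9))
            blk.eval()
            outs[(add1, add2)] = blk(x).data
            assert outs[(add1, add2)].shape == (1, 20, 8, 8)
    vals = list(outs.values())
    assert len({v.tobytes() for v in vals}) == 4   # all four settings distinct


def test_lmlp_rejects_excessive_shift():
    blk = LMLPBlock(LmlpConfig(10, shift_size=8), rng=_rng())
    with pytest.raises(ValueError, match="shift"):
        blk(_x((1, 10, 4, 4)))


# ---------------------------------------------------------------------------
# gradient flow through every block
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("factory,cin", [
    (lambda rng: LDABlock(LdaConfig(3, 8, stride=2), rng=rng), 3),
    (lambda rng: LDABlock(LdaConfig(4, 8, use_se=True, se_reduction=2), rng=rng), 4),
    (lambda rng: LMLPBlock(LmlpConfig(8), rng=rng), 8),
    (lambda rng: DepthwiseSeparableConv(4, 8, rng=rng), 4),
    (lambda rng: AsymmetricConvPair(6, rng=rng), 6),
], ids=["lda_a", "lda_b", "lmlp", "dwsep", "asym"])
def test_every_weight_receives_finite_nonzero_gradient(factory, cin):
    blk = factory(_rng(11))
    x = _x((2, cin, 8, 8), seed=3)
    out = blk(x)
    target = (_rng(4).random(out.shape) > 0.5).astype(np.float32)
    loss = dice_bce_loss(T.sigmoid(out), target)
    loss.backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None, f"{name} got no gradient"
        assert np.all(np.isfinite(p.grad)), f"{name} gradient not finite"
        assert np.any(p.grad != 0.0), f"{name} gradient identically zero"
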