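"""The autograd engine against brute-force forwards and numeric gradients."""

import numpy as np
import pytest

import lcmunet.tensor as T
from lcmunet.tensor import Tensor

from oracles import conv2d_naive, numeric_gradient


def _check_grad(op, *arrays, tol=2e-2, eps=1e-3):
    """Compare analytic gradients of sum(op(...)) with central differences."""
    tensors = [Tensor(a.astype(np.float32), requires_grad=True) for a in arrays]
    out = op(*tensors)
    loss = T.tsum(out * out)   # quadratic head exercises nonlinear paths
    loss.backward()
    for i, (arr, t) in enumerate(zip(arrays, tensors)):
        def f(x, i=i):
            ts = [Tensor(a.astype(np.float32)) for a in arrays]
            ts[i] = Tensor(x.astype(np.float32))
            o = op(*ts)
            return float((o.data.astype(np.float64) ** 2).sum())
        num = numeric_gradient(f, arr.astype(np.float64), eps=eps)
        scale = max(np.abs(num).max(), 1.0)
        assert np.allclose(t.grad, num, atol=tol * scale), \
            f"gradient mismatch (max err {np.abs(t.grad - num).max()})"


@pytest.mark.parametrize("cin,cout,k,stride,groups", [
    (3, 4, 3, 1, 1),
    (4, 6, 1, 1, 1),
    (4, 4, 3, 1, 4),       # depthwise
    (6, 6, (1, 3), 1, 6),  # depthwise asymmetric
    (4, 8, 3, 2, 2),       # grouped strided
])
def test_conv2d_matches_naive_and_gradients(rng, cin, cout, k, stride, groups):
    kh, kw = (k, k) if isinstance(k, int) else k
    x = rng.standard_normal((2, cin, 6, 6))
    w = rng.standard_normal((cout, cin // groups, kh, kw)) * 0.5
    b = rng.standard_normal(cout) * 0.1
    pad = ((kh - 1) // 2, (kw - 1) // 2)
    ref = conv2d_naive(x, w, b, stride=stride, padding=pad, groups=groups)
    out = T.conv2d(Tensor(x), Tensor(w), Tensor(b),
                   stride=stride, padding=pad, groups=groups)
    assert np.allclose(out.data, ref, atol=1e-4)
    _check_grad(lambda xx, ww, bb: T.conv2d(xx, ww, bb, stride=stride,
                                            padding=pad, groups=groups),
                x, w, b)


def test_conv2d_rejects_channel_mismatch(rng):
    x = Tensor(rng.standard_normal((1, 3, 4, 4)))
    w = Tensor(rng.standard_normal((8, 5, 1, 1)))
    with pytest.raises(ValueError, match="channel mismatch"):
        T.conv2d(x, w)


def test_conv_transpose2d_forward_and_grad(rng):
    x = rng.standard_normal((2, 3, 4, 4))
    w = rng.standard_normal((3, 5, 2, 2)) * 0.5
    out = T.conv_transpose2d(Tensor(x), Tensor(w))
    # brute force: scatter each input pixel into a 2x2 output tile
    ref = np.zeros((2, 5, 8, 8))
    for n in range(2):
        for c in range(3):
            for i in range(4):
                for j in range(4):
                    ref[n, :, 2 * i:2 * i + 2, 2 * j:2 * j + 2] += \
                        x[n, c, i, j] * w[c]
    assert np.allclose(out.data, ref, atol=1e-4)
    _check_grad(lambda xx, ww: T.conv_transpose2d(xx, ww), x, w)


def test_batch_norm_train_mode_statistics_and_grad(rng):
    x = rng.standard_normal((4, 3, 5, 5)) * 2 + 1
    g = rng.standard_normal(3)
    b = rng.standard_normal(3)

    def op(xx, gg, bb):
        return T.batch_norm2d(xx, gg, bb, np.zeros(3, np.float32),
                              np.ones(3, np.float32), training=True)
    out = op(Tensor(x), Tensor(g), Tensor(b))
    assert np.allclose(out.data.mean(axis=(0, 2, 3)), b, atol=1e-4)
    # larger step: the normalised forward is float32, so tiny eps is noisy
    _check_grad(op, x, g, b, tol=3e-2, eps=1e-2)


def test_batch_norm_eval_uses_running_stats(rng):
    x = rng.standard_normal((2, 3, 4, 4))
    rm = np.array([1.0, -1.0, 0.5], np.float32)
    rv = np.array([4.0, 1.0, 2.25], np.float32)
    out = T.batch_norm2d(Tensor(x), Tensor(np.ones(3)), Tensor(np.zeros(3)),
                         rm, rv, training=False)
    expected = (x - rm[None, :, None, None]) / np.sqrt(rv + 1e-5)[None, :, None, None]
    assert np.allclose(out.data, expected, atol=1e-5)


def test_layer_norm_channels_grad(rng):
    x = rng.standard_normal((2, 5, 3, 3))
    g = rng.standard_normal(5)
    b = rng.standard_normal(5)
    _check_grad(lambda xx, gg, bb: T.layer_norm_channels(xx, gg, bb), x, g, b)


def test_upsample_gradient(rng):
    x = rng.standard_normal((2, 3, 6, 6))
    _check_grad(T.upsample_bilinear2x, x)


def test_max_pool_backward_scatters_to_argmax(rng):
    # numeric differencing is invalid at the max kink; check the scatter law
    x = Tensor(rng.standard_normal((2, 3, 6, 6)), requires_grad=True)
    out = T.max_pool2x2(x)
    T.tsum(out * out).backward()
    windows = x.data.reshape(2, 3, 3, 2, 3, 2).transpose(0, 1, 2, 4, 3, 5)
    expected = np.zeros_like(x.grad)
    for idx in np.ndindex(2, 3, 3, 3):
        n, c, i, j = idx
        w = windows[n, c, i, j]
        a, b = np.unravel_index(w.argmax(), (2, 2))
        expected[n, c, 2 * i + a, 2 * j + b] = 2.0 * w.max()
    assert np.allclose(x.grad, expected, atol=1e-5)


def test_max_pool_rejects_odd_sizes(rng):
    with pytest.raises(ValueError, match="even"):
        T.max_pool2x2(Tensor(rng.standard_normal((1, 1, 5, 6))))


def test_upsample_bilinear_preserves_constant(rng):
    x = Tensor(np.full((1, 2, 4, 4), 3.25, np.float32))
    out = T.upsample_bilinear2x(x)
    assert out.shape == (1, 2, 8, 8)
    assert np.allclose(out.data, 3.25)


def test_axial_shift_roundtrip_and_grad(rng):
    x = rng.standard_normal((2, 6, 5, 5))
    offsets = np.array([-2, -1, 0, 0, 1, 2])
    out = T.axial_shift(Tensor(x), offsets, axis=3)
    # channel 2 (offset 0) untouched; channel 5 shifted right by 2, zero-filled
    assert np.allclose(out.data[:, 2], x[:, 2])
    assert np.allclose(out.data[:, 5, :, 2:], x[:, 5, :, :3])
    assert np.allclose(out.data[:, 5, :, :2], 0.0)
    _check_grad(lambda xx: T.axial_shift(xx, offsets, axis=2), x)


def test_pointwise_ops_gradients(rng):
    x = rng.standard_normal((3, 4)) * 1.5
    _check_grad(T.relu, x + 0.05)          # keep away from the kink
    _check_grad(T.sigmoid, x)
    _check_grad(T.gelu, x)
    _check_grad(lambda xx: T.log(T.sigmoid(xx)), x)
    _check_grad(T.tmean, x)


def test_linear_and_se_style_scaling_grad(rng):
    x = rng.standard_normal((3, 6))
    w = rng.standard_normal((4, 6)) * 0.5
    b = rng.standard_normal(4) * 0.1
    _check_grad(lambda xx, ww, bb: T.linear(xx, ww, bb), x, w, b)
    xm = rng.standard_normal((2, 3, 4, 4))
    s = rng.uniform(0.1, 0.9, (2, 3))
    _check_grad(lambda xx, ss: T.scale_channels(xx, T.sigmoid(ss)), xm, s)
    _check_grad(T.global_avg_pool, xm)


def test_broadcast_add_mul_unbroadcasts_gradients(rng):
    a = rng.standard_normal((2, 3, 4))
    c = rng.standard_normal((1, 3, 1))
    _check_grad(lambda aa, cc: aa * cc + cc, a, c)


def test_backward_requires_scalar(rng):
    x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    with pytest.raises(ValueError, match="scalar"):
        (x * 2.0).backward()


def test_mac_counter_counts_conv_and_linear_only(rng):
    x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
    w = Tensor(rng.standard_normal((6, 4, 3, 3)).astype(np.float32))
    with T.count_macs() as box:
        out = T.conv2d(x, w, padding=(1, 1))
        T.relu(out)                       # free under the MAC convention
        T.max_pool2x2(out)                # also free
    assert box[0] == 9 * 4 * 6 * 8 * 8
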