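"""Independent oracles: closed-form parameter/MAC counts and brute-force ops.

These are written from the block definitions alone (kernel shapes, channel
schedules) and never touch the package's enumeration or tracing code, so
they can serve as an independent cross-check in tests.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# closed-form parameter counts
# ---------------------------------------------------------------------------

BN = lambda c: 2 * c  # noqa: E731


def conv_params(cin: int, cout: int, kh: int, kw: int | None = None,
                groups: int = 1, bias: bool = False) -> int:
    kw = kh if kw is None else kw
    return kh * kw * (cin // groups) * cout + (cout if bias else 0)


def dwsep_params(cin: int, cout: int, k: int = 3, with_bn: bool = True) -> int:
    p = conv_params(cin, cin, k, groups=cin) + conv_params(cin, cout, 1)
    return p + (BN(cin) + BN(cout) if with_bn else 0)


def asym_pair_params(c: int, k: int = 3, depthwise: bool = False,
                     with_bn: bool = True) -> int:
    g = c if depthwise else 1
    p = conv_params(c, c, 1, k, groups=g) + conv_params(c, c, k, 1, groups=g)
    return p + (2 * BN(c) if with_bn else 0)


def se_params(c: int, r: int) -> int:
    return c * (c // r) + c // r + (c // r) * c + c


def default_se_r(c: int) -> int:
    return 2 if c <= 128 else 4


def lda_params(a: int, b: int, use_se: bool = False, r: int | None = None,
               k_dw: int = 5, k_asym: int = 5, k_short: int = 3) -> int:
    p = conv_params(a, b, 1) + BN(b)                       # 1x1 channel map
    p += conv_params(b, b, k_dw, groups=b) + BN(b)         # depthwise
    p += conv_params(a, b, 1) + BN(b)                      # input projection
    p += conv_params(b, b, 1) + BN(b)                      # part-II 1x1
    p += asym_pair_params(b, k_asym, depthwise=True)       # 1xk + kx1
    p += conv_params(b, b, k_short, groups=b) + BN(b)      # part-II shortcut
    if use_se:
        p += se_params(b, r if r is not None else default_se_r(b))
    return p


def lmlp_params(c: int, hidden: int | None = None, dw_k: int = 3) -> int:
    h = hidden if hidden is not None else max(1, int(round(0.25 * c)))
    p = conv_params(c, c, 1, bias=True)                    # tokenizer
    p += 2 * (c * h + h + h * c + c)                       # two token MLPs
    p += 2 * (conv_params(c, c, dw_k, groups=c) + c)       # two dw convs, biased
    p += 2 * c                                             # layer norm
    return p


def lmlp_stage_params(a: int, b: int) -> int:
    return conv_params(a, b, 3) + BN(b) + lmlp_params(b)


# stage tables: (kind, in, out); sides relative to input H (divisors)
_LCM_LDA = [("A", 3, 16, 1), ("B", 16, 32, 2), ("B", 32, 128, 4),
            ("B", 128, 32, 8), ("B", 32, 16, 4), ("A", 16, 3, 2)]
_LCM_MLP = [(128, 160, 16), (160, 256, 32), (256, 160, 32), (160, 128, 16)]
_ALL_LDA = [(3, 16, 1), (16, 32, 2), (32, 128, 4), (128, 160, 8), (160, 256, 16),
            (256, 160, 32), (160, 128, 16), (128, 32, 8), (32, 16, 4), (16, 3, 2)]
_SKIPS = [(160, 16), (128, 8), (32, 4), (16, 2)]    # (channels, side divisor)


def _common_params() -> int:
    return sum(c * c + c for c, _ in _SKIPS) + (3 * 1 + 1)


def lcmunet_total_params() -> int:
    p = sum(lda_params(a, b, use_se=(k == "B")) for k, a, b, _ in _LCM_LDA)
    p += sum(lmlp_stage_params(a, b) for a, b, _ in _LCM_MLP)
    return p + _common_params()


def all_lda_a_total_params() -> int:
    p = sum(lda_params(a, b) for a, b, _ in _ALL_LDA)
    return p + _common_params()


def lda_a_plus_b_total_params() -> int:
    p = 0
    for i, (a, b, _) in enumerate(_ALL_LDA):
        first_level = i in (0, len(_ALL_LDA) - 1)
        p += lda_params(a, b, use_se=not first_level)
    return p + _common_params()


def lda_a_plus_lmlp_total_params() -> int:
    p = sum(lda_params(a, b) for _, a, b, _ in _LCM_LDA)
    p += sum(lmlp_stage_params(a, b) for a, b, _ in _LCM_MLP)
    return p + _common_params()


def unet_total_params() -> int:
    def dc(a, b):
        return 9 * a * b + BN(b) + 9 * b * b + BN(b)
    ch = [64, 128, 256, 512, 1024]
    p = dc(3, ch[0]) + dc(*ch[0:2]) + dc(*ch[1:3]) + dc(*ch[2:4]) + dc(*ch[3:5])
    for big in (1024, 512, 256, 128):
        p += 4 * big * (big // 2) + big // 2       # transposed conv 2x2
        p += dc(big, big // 2)                     # after concat
    return p + 64 + 1


# ---------------------------------------------------------------------------
# closed-form MAC counts (MAC = 1 FLOP; convs and linears only)
# ---------------------------------------------------------------------------

def lda_macs(a: int, b: int, n2: int, use_se: bool = False,
             r: int | None = None) -> int:
    per_px = a * b + 25 * b + a * b + b * b + 5 * b + 5 * b + 9 * b
    m = per_px * n2
    if use_se:
        rr = r if r is not None else default_se_r(b)
        m += 2 * b * (b // rr)
    return m


def lmlp_stage_macs(a: int, b: int, n2: int) -> int:
    h = max(1, int(round(0.25 * b)))
    per_px = 9 * a * b + b * b + 2 * (2 * b * h) + 2 * 9 * b
    return per_px * n2


def lcmunet_total_macs(hw: tuple[int, int] = (256, 256)) -> int:
    H, W = hw
    m = sum(lda_macs(a, b, (H // d) * (W // d), use_se=(k == "B"))
            for k, a, b, d in _LCM_LDA)
    m += sum(lmlp_stage_macs(a, b, (H // d) * (W // d)) for a, b, d in _LCM_MLP)
    m += sum(c * c * (H // d) * (W // d) for c, d in _SKIPS)
    m += 3 * H * W
    return m


def unet_total_macs(hw: tuple[int, int] = (256, 256)) -> int:
    H, W = hw
    ch = [64, 128, 256, 512, 1024]

    def dc(a, b, n2):
        return (9 * a * b + 9 * b * b) * n2
    m = dc(3, ch[0], H * W)
    for lvl, (a, b) in enumerate(zip(ch[:-1], ch[1:]), start=1):
        m += dc(a, b, (H >> lvl) * (W >> lvl))
    for lvl, big in zip((3, 2, 1, 0), (1024, 512, 256, 128)):
        n2 = (H >> lvl) * (W >> lvl)
        m += 4 * big * (big // 2) * n2             # transposed conv at out res
        m += dc(big, big // 2, n2)
    return m + 64 * 1 * H * W


# ---------------------------------------------------------------------------
# brute-force references
# ---------------------------------------------------------------------------

def conv2d_naive(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                 stride: int = 1, padding: tuple[int, int] = (0, 0),
                 groups: int = 1) -> np.ndarray:
    """Direct-loop convolution for tiny inputs."""
    N, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    ph, pw = padding
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho = (H + 2 * ph - kh) // stride + 1
    Wo = (W + 2 * pw - kw) // stride + 1
    out = np.zeros((N, Co, Ho, Wo))
    cpg = C // groups
    opg = Co // groups
    for n in range(N):
        for o in range(Co):
            g = o // opg
            for i in range(Ho):
                for j in range(Wo):
                    patch = xp[n, g * cpg:(g + 1) * cpg,
                               i * stride:i * stride + kh,
                               j * stride:j * stride + kw]
                    out[n, o, i, j] = (patch * w[o]).sum()
    if b is not None:
        out += b[None, :, None, None]
    return out


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
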