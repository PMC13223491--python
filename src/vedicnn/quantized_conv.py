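"""Convolution / batch-norm / ReLU with selectable arithmetic backends.

The accelerator computes each output pixel as an inner product between an
input patch vector and a filter vector: every scalar multiply goes through
the emulated floating-point multiplier and the partial products are summed
by a balanced binary adder tree.  Three backends are exposed:

* ``exact``      — host float64 arithmetic (the oracle);
* ``cutin_fp32`` — every multiply is the emulated IEEE-754 fp32 multiply on
  the CUTIN datapath and every add the CSCGL-based fp32 add;
* ``cutin_fp16`` — same datapath in the binary16 profile.

Feature maps are H×W×C ``numpy`` arrays, channel-last.  Symmetric
quantization (zero point fixed at 0) to 8 or 16 bit levels is provided for
the quantized datapath experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import float_emulation as fe
from .float_emulation import FP16, FP32, FloatBits, RoundingMode

__all__ = [
    "QuantParams", "ConvLayerSpec", "BACKENDS",
    "quantize", "dequantize", "conv2d", "batch_norm", "relu",
    "inner_product_error_bound",
]

BACKENDS = ("exact", "cutin_fp32", "cutin_fp16")


@dataclass(frozen=True)
class QuantParams:
    """Symmetric quantization parameters (zero point is fixed at 0)."""

    bits: int
    scale: float
    zero_point: int = 0

    def __post_init__(self) -> None:
        if self.bits not in (8, 16):
            raise ValueError("bits must be 8 or 16")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.zero_point != 0:
            raise ValueError("symmetric quantization requires zero_point == 0")


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: int = 0
    backend: str = "exact"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd and positive")
        if min(self.in_channels, self.out_channels, self.stride) < 1:
            raise ValueError("channels and stride must be positive")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.padding - self.kernel) // self.stride + 1
        ow = (w + 2 * self.padding - self.kernel) // self.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("kernel does not fit the padded input")
        return oh, ow


def quantize(t: np.ndarray, bits: int = 8) -> tuple[np.ndarray, QuantParams]:
    """Symmetric per-tensor quantization to ``bits``-bit integer levels.

    ``scale = max|t| / (2^(bits-1) - 1)``; levels are rounded and clipped to
    the symmetric range.  An all-zero tensor gets scale 1 by convention.
    """
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise ValueError("quantize requires finite input")
    qmax = (1 << (bits - 1)) - 1
    peak = float(np.max(np.abs(t)))
    scale = peak / qmax if peak > 0 else 1.0
    levels = np.clip(np.round(t / scale), -qmax, qmax).astype(np.int32)
    return levels, QuantParams(bits=bits, scale=scale)


def dequantize(levels: np.ndarray, qp: QuantParams) -> np.ndarray:
    return levels.astype(np.float64) * qp.scale


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x); idempotent."""
    return np.maximum(x, 0.0)


def batch_norm(x: np.ndarray, mean, var, gamma, beta,
               eps: float = 1e-5) -> np.ndarray:
    """Per-channel normalization ``(x - mean)/sqrt(var + eps) * gamma + beta``."""
    mean = np.asarray(mean, dtype=np.float64)
    var = np.asarray(var, dtype=np.float64)
    if np.any(var < 0):
        raise ValueError("variance must be non-negative")
    return (x - mean) / np.sqrt(var + eps) * np.asarray(gamma) + np.asarray(beta)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, padding: int) -> np.ndarray:
    """Patch matrix of shape (OH*OW, k*k*C) for a H×W×C input."""
    h, w, c = x.shape
    xp = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    oh = (h + 2 * padding - k) // stride + 1
    ow = (w + 2 * padding - k) // stride + 1
    cols = np.empty((oh * ow, k * k * c), dtype=x.dtype)
    idx = 0
    for i in range(oh):
        for j in range(ow):
            patch = xp[i * stride:i * stride + k, j * stride:j * stride + k, :]
            cols[idx] = patch.reshape(-1)
            idx += 1
    return cols


def _tree_sum_emulated(vals: list[FloatBits], rm: RoundingMode) -> FloatBits:
    """Balanced binary adder tree over emulated floats."""
    while len(vals) > 1:
        nxt = []
        for i in range(0, len(vals) - 1, 2):
            nxt.append(fe.fp_add(vals[i], vals[i + 1], rm))
        if len(vals) % 2:
            nxt.append(vals[-1])
        vals = nxt
    return vals[0]


def conv2d(x: np.ndarray, weights: np.ndarray, spec: ConvLayerSpec,
           bias: np.ndarray | None = None,
           rounding: RoundingMode = RoundingMode.ROUND_NEAREST_EVEN) -> np.ndarray:
    """2-D convolution (cross-correlation) of a H×W×C map.

    ``weights`` has shape (k, k, in_channels, out_channels).  With the
    ``exact`` backend the patch/filter inner products are host matmuls; the
    ``cutin_*`` backends push every scalar product through the emulated
    floating-point multiplier and sum them with a balanced tree of emulated
    adds, mirroring the accelerator datapath.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("input must be H×W×C")
    k, k2, cin, cout = weights.shape
    if k != spec.kernel or k2 != spec.kernel or cin != spec.in_channels \
            or cout != spec.out_channels:
        raise ValueError("weight shape inconsistent with layer spec")
    if x.shape[2] != cin:
        raise ValueError("input channel count does not match spec")
    oh, ow = spec.out_size(x.shape[0], x.shape[1])
    cols = _im2col(x, k, spec.stride, spec.padding)          # (OH*OW, kkC)
    wmat = weights.reshape(k * k * cin, cout)                # (kkC, cout)

    if spec.backend == "exact":
        out = cols @ wmat
    else:
        profile = FP32 if spec.backend == "cutin_fp32" else FP16
        wf = [[fe.from_float(float(wmat[t, o]), profile)
               for t in range(wmat.shape[0])] for o in range(cout)]
        out = np.empty((cols.shape[0], cout))
        for r in range(cols.shape[0]):
            row = [fe.from_float(float(v), profile) for v in cols[r]]
            for o in range(cout):
                prods = [fe.fp_multiply(a, b, rounding)
                         for a, b in zip(row, wf[o])]
                out[r, o] = fe.to_float(_tree_sum_emulated(prods, rounding))
    if bias is not None:
        out = out + np.asarray(bias).reshape(1, cout)
    return out.reshape(oh, ow, cout)


def inner_product_error_bound(x: np.ndarray, w: np.ndarray,
                              profile=FP32,
                              rounding: RoundingMode = RoundingMode.ROUND_NEAREST_EVEN
                              ) -> float:
    """Analytic bound on |emulated − exact| for one inner product.

    Each emulated multiply errs by at most u (truncate) or u/2 (RNE) in
    relative terms, with u one ulp at the product's magnitude; a balanced
    adder tree of depth d adds at most d further half-ulp (RNE) or ulp
    (truncate) relative errors.  The bound below is the standard first-order
    accumulation estimate, padded for fp16's flush-to-zero floor.
    """
    m = x.size
    u = 2.0 ** (-profile.mant_bits)
    per_op = u if rounding is RoundingMode.TRUNCATE else u / 2.0
    depth = max(1, math.ceil(math.log2(max(m, 2))))
    mag_sum = float(np.sum(np.abs(x.reshape(-1) * w.reshape(-1))))
    # flush-to-zero floor: products below the smallest normal vanish entirely
    min_normal = 2.0 ** (1 - profile.bias)
    return (1 + depth) * per_op * mag_sum * 1.05 + m * min_normal
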