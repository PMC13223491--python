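"""IEEE-754 floating-point multiply/add emulated on the Vedic integer units.

The significand product is computed by :func:`vedicnn.bitvec_arith.cutin_multiply`
(24×24 → 48 bits in the fp32 profile, 11×11 → 22 bits in fp16) and mantissa
additions go through the CSCGL adder.  Normalization follows the accelerator's
rule: when the MSB of the double-width product is set the mantissa window
starts one bit higher and the exponent is incremented; otherwise the window
starts at the next bit and the exponent is unchanged.

Deviations from full IEEE-754 semantics, by design:

* subnormals are flushed to signed zero on input and output (the datapath
  handles biased exponents 1..254 only);
* exponent overflow saturates to the largest finite magnitude instead of
  producing an infinity (flagged);
* default rounding is truncation of the dropped low bits ("the extra bits
  are eliminated"); round-nearest-even is available for reference
  comparisons against host IEEE arithmetic.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field

from .bitvec_arith import BitVector, cutin_multiply, _cscgl_int

__all__ = [
    "Profile", "FP32", "FP16", "FloatBits", "RoundingMode", "FpFlags",
    "decode", "encode", "from_float", "to_float",
    "fp_multiply", "fp_add", "ulp_diff",
]


@dataclass(frozen=True)
class Profile:
    name: str
    total_bits: int
    exp_bits: int
    mant_bits: int

    @property
    def bias(self) -> int:
        return (1 << (self.exp_bits - 1)) - 1

    @property
    def exp_max(self) -> int:
        return (1 << self.exp_bits) - 1

    @property
    def sig_bits(self) -> int:
        # stored mantissa + hidden bit
        return self.mant_bits + 1

    @property
    def mul_width(self) -> int:
        # power-of-two CUTIN datapath width holding the significand
        w = 4
        while w < self.sig_bits:
            w *= 2
        return w


FP32 = Profile("fp32", 32, 8, 23)
FP16 = Profile("fp16", 16, 5, 10)


class RoundingMode(enum.Enum):
    TRUNCATE = "truncate"
    ROUND_NEAREST_EVEN = "rne"


@dataclass
class FpFlags:
    """Sticky status flags accumulated across emulated operations."""

    overflow: bool = False
    underflow: bool = False
    inexact: bool = False
    flushed_subnormal: bool = False


@dataclass(frozen=True)
class FloatBits:
    """Sign/exponent/mantissa decomposition of an IEEE-754 bit pattern."""

    sign: int
    exponent: int
    mantissa: int
    profile: Profile = FP32

    def __post_init__(self) -> None:
        p = self.profile
        if self.sign not in (0, 1):
            raise ValueError("sign must be 0 or 1")
        if not 0 <= self.exponent <= p.exp_max:
            raise ValueError("exponent out of field range")
        if not 0 <= self.mantissa < (1 << p.mant_bits):
            raise ValueError("mantissa out of field range")

    @property
    def kind(self) -> str:
        p = self.profile
        if self.exponent == 0:
            return "zero" if self.mantissa == 0 else "subnormal"
        if self.exponent == p.exp_max:
            return "inf" if self.mantissa == 0 else "nan"
        return "normal"


def decode(pattern: int, profile: Profile = FP32) -> FloatBits:
    """Extract sign/exponent/mantissa fields from a raw bit pattern."""
    p = profile
    if not 0 <= pattern < (1 << p.total_bits):
        raise ValueError("pattern does not fit the profile width")
    mant = pattern & ((1 << p.mant_bits) - 1)
    exp = (pattern >> p.mant_bits) & p.exp_max
    sign = pattern >> (p.total_bits - 1)
    return FloatBits(sign, exp, mant, p)


def encode(fb: FloatBits) -> int:
    p = fb.profile
    return (fb.sign << (p.total_bits - 1)) | (fb.exponent << p.mant_bits) | fb.mantissa


def from_float(x: float, profile: Profile = FP32) -> FloatBits:
    """Host-rounded conversion of a Python float into a profile pattern."""
    if profile.total_bits == 32:
        (pattern,) = struct.unpack("<I", struct.pack("<f", x))
    else:
        (pattern,) = struct.unpack("<H", struct.pack("<e", x))
    return decode(pattern, profile)


def to_float(fb: FloatBits) -> float:
    if fb.profile.total_bits == 32:
        return struct.unpack("<f", struct.pack("<I", encode(fb)))[0]
    return struct.unpack("<e", struct.pack("<H", encode(fb)))[0]


def ulp_diff(a: FloatBits, b: FloatBits) -> int:
    """Distance in representable steps between two same-profile patterns."""
    if a.profile is not b.profile and a.profile.name != b.profile.name:
        raise ValueError("profiles differ")

    def ordered(fb: FloatBits) -> int:
        v = encode(fb)
        top = 1 << (fb.profile.total_bits - 1)
        return (top - (v - top)) if v & top else top + v

    return abs(ordered(a) - ordered(b))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _flush(fb: FloatBits, flags: FpFlags | None) -> FloatBits:
    if fb.kind == "subnormal":
        if flags is not None:
            flags.flushed_subnormal = True
        return FloatBits(fb.sign, 0, 0, fb.profile)
    return fb


def _saturate(sign: int, p: Profile, flags: FpFlags | None) -> FloatBits:
    if flags is not None:
        flags.overflow = True
    return FloatBits(sign, p.exp_max - 1, (1 << p.mant_bits) - 1, p)


def _underflow(sign: int, p: Profile, flags: FpFlags | None) -> FloatBits:
    if flags is not None:
        flags.underflow = True
    return FloatBits(sign, 0, 0, p)


def _nan(p: Profile) -> FloatBits:
    return FloatBits(0, p.exp_max, 1 << (p.mant_bits - 1), p)


def _round_sig(sig: int, dropped: int, drop_bits: int,
               rm: RoundingMode, flags: FpFlags | None) -> tuple[int, bool]:
    """Round ``sig`` given the ``drop_bits`` low bits that fell off.

    Returns (rounded significand, carried-into-next-bit flag unused by
    caller; overflow of the significand field is detected by the caller).
    """
    if dropped and flags is not None:
        flags.inexact = True
    if rm is RoundingMode.TRUNCATE or drop_bits == 0:
        return sig, False
    half = 1 << (drop_bits - 1)
    if dropped > half or (dropped == half and (sig & 1)):
        return sig + 1, True
    return sig, False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fp_multiply(x: FloatBits, y: FloatBits,
                rm: RoundingMode = RoundingMode.TRUNCATE,
                flags: FpFlags | None = None) -> FloatBits:
    """Multiply two floats; the significand product runs on CUTIN.

    Sign is the XOR of the operand signs; the biased result exponent is
    ``ex + ey - bias`` adjusted by the normalization of the double-width
    significand product: MSB set -> take the mantissa window one bit higher
    and increment the exponent, MSB clear -> window from the next position,
    exponent unchanged.
    """
    p = x.profile
    if y.profile.name != p.name:
        raise ValueError("operand profiles differ")
    sign = x.sign ^ y.sign
    kx, ky = x.kind, y.kind
    if kx == "nan" or ky == "nan":
        return _nan(p)
    if kx == "inf" or ky == "inf":
        if (kx in ("zero", "subnormal")) or (ky in ("zero", "subnormal")):
            return _nan(p)  # inf * 0
        return FloatBits(sign, p.exp_max, 0, p)
    x = _flush(x, flags)
    y = _flush(y, flags)
    if x.kind == "zero" or y.kind == "zero":
        return FloatBits(sign, 0, 0, p)

    s = p.sig_bits
    w = p.mul_width
    sig_x = (1 << p.mant_bits) | x.mantissa
    sig_y = (1 << p.mant_bits) | y.mantissa
    prod = int(cutin_multiply(BitVector(w, sig_x), BitVector(w, sig_y)))
    # product of two s-bit significands lies in [2^(2s-2), 2^(2s-1))∪…2^(2s)-…
    msb_pos = 2 * s - 1
    if prod >> msb_pos:          # leading bit of the product is high
        drop = s
        exp_adj = 1
    else:                        # leading bit zero: window from (n-2)
        drop = s - 1
        exp_adj = 0
    sig = prod >> drop
    dropped = prod & ((1 << drop) - 1)
    sig, _ = _round_sig(sig, dropped, drop, rm, flags)
    if sig >> s:                 # rounding carried out of the window
        sig >>= 1
        exp_adj += 1
    exp = x.exponent + y.exponent - p.bias + exp_adj
    if exp >= p.exp_max:
        return _saturate(sign, p, flags)
    if exp <= 0:
        return _underflow(sign, p, flags)
    return FloatBits(sign, exp, sig & ((1 << p.mant_bits) - 1), p)


def fp_add(x: FloatBits, y: FloatBits,
           rm: RoundingMode = RoundingMode.ROUND_NEAREST_EVEN,
           flags: FpFlags | None = None) -> FloatBits:
    """Align-add-normalize floating addition; mantissa adds run on CSCGL.

    Three guard/round/sticky bits carry the shifted-out precision, which is
    what makes the round-nearest-even path bit-exact against host IEEE
    arithmetic.
    """
    p = x.profile
    if y.profile.name != p.name:
        raise ValueError("operand profiles differ")
    kx, ky = x.kind, y.kind
    if kx == "nan" or ky == "nan":
        return _nan(p)
    if kx == "inf" or ky == "inf":
        if kx == "inf" and ky == "inf" and x.sign != y.sign:
            return _nan(p)
        return x if kx == "inf" else y
    x = _flush(x, flags)
    y = _flush(y, flags)
    if x.kind == "zero" and y.kind == "zero":
        return FloatBits(x.sign & y.sign, 0, 0, p)
    if x.kind == "zero":
        return y
    if y.kind == "zero":
        return x

    # order so |x| >= |y|
    if (x.exponent, x.mantissa) < (y.exponent, y.mantissa):
        x, y = y, x
    s = p.sig_bits
    sig_x = ((1 << p.mant_bits) | x.mantissa) << 3   # 3 GRS bits
    sig_y = ((1 << p.mant_bits) | y.mantissa) << 3
    d = x.exponent - y.exponent
    if d >= s + 3:
        small = 1                                    # pure sticky
    else:
        small = sig_y >> d
        if sig_y & ((1 << d) - 1):
            small |= 1
    exp = x.exponent
    wa = s + 3
    if x.sign == y.sign:
        total = _cscgl_int(sig_x, small, 0, wa)
        sign = x.sign
        if total >> wa:                              # carry out: renormalize
            sticky = total & 1
            total = (total >> 1) | sticky
            exp += 1
    else:
        # magnitude subtraction via two's complement on the CSCGL unit
        mask = (1 << wa) - 1
        total = _cscgl_int(sig_x, (~small) & mask, 1, wa) & mask
        sign = x.sign
        if total == 0:
            return FloatBits(0, 0, 0, p)             # exact cancellation -> +0
        # normalize left; the sticky bit stays at position 0 while the
        # higher GRS bits shift up (bits below sticky remain below it)
        while not (total >> (wa - 1)):
            total = ((total & ~1) << 1) | (total & 1)
            exp -= 1
            if exp <= 0:
                return _underflow(sign, p, flags)
    sig = total >> 3
    dropped = total & 0x7
    sig, _ = _round_sig(sig, dropped, 3, rm, flags)
    if sig >> s:
        sig >>= 1
        exp += 1
    if exp >= p.exp_max:
        return _saturate(sign, p, flags)
    if exp <= 0:
        return _underflow(sign, p, flags)
    return FloatBits(sign, exp, sig & ((1 << p.mant_bits) - 1), p)
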