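"""Tests of the emulated IEEE-754 multiply/add against host arithmetic."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vedicnn.float_emulation import (
    FP16,
    FP32,
    FloatBits,
    FpFlags,
    RoundingMode,
    decode,
    encode,
    fp_add,
    fp_multiply,
    from_float,
    to_float,
    ulp_diff,
)

RNE = RoundingMode.ROUND_NEAREST_EVEN
TRUNC = RoundingMode.TRUNCATE


def normal32(rng, lo=97, hi=157):
    """Random finite normal fp32 with moderate exponent (products stay normal)."""
    return decode((rng.randint(0, 1) << 31) | (rng.randint(lo, hi) << 23)
                  | rng.getrandbits(23), FP32)


def normal16(rng, lo=10, hi=20):
    return decode((rng.randint(0, 1) << 15) | (rng.randint(lo, hi) << 10)
                  | rng.getrandbits(10), FP16)


class TestCodec:
    @pytest.mark.parametrize("pattern, value", [
        (0x3F800000, 1.0),
        (0x00000000, 0.0),
        (0xC0400000, -3.0),
        (0x40490FDB, 3.1415927410125732),
    ])
    def test_canonical_patterns(self, pattern, value):
        fb = decode(pattern, FP32)
        assert to_float(fb) == value
        assert encode(fb) == pattern

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=300, derandomize=True)
    def test_round_trip_all_patterns(self, pattern):
        assert encode(decode(pattern, FP32)) == pattern

    @given(st.integers(0, 2**16 - 1))
    @settings(max_examples=300, derandomize=True)
    def test_round_trip_fp16(self, pattern):
        assert encode(decode(pattern, FP16)) == pattern

    def test_classification(self):
        assert decode(0x7F800000).kind == "inf"
        assert decode(0x7FC00000).kind == "nan"
        assert decode(0x00000001).kind == "subnormal"
        assert decode(0x3F800000).kind == "normal"


class TestMultiply:
    def test_exact_small_product(self):
        for rm in (RNE, TRUNC):
            r = fp_multiply(from_float(1.5), from_float(2.0), rm)
            assert to_float(r) == 3.0

    def test_multiplicative_identity(self):
        rng = random.Random(7)
        one = from_float(1.0)
        for _ in range(200):
            x = normal32(rng)
            assert encode(fp_multiply(x, one, RNE)) == encode(x)

    def test_commutativity_bit_exact(self):
        rng = random.Random(8)
        for _ in range(200):
            x, y = normal32(rng), normal32(rng)
            for rm in (RNE, TRUNC):
                assert encode(fp_multiply(x, y, rm)) == \
                    encode(fp_multiply(y, x, rm))

    def test_rne_bit_equals_host_sampled(self):
        rng = random.Random(9)
        for _ in range(2000):
            x, y = normal32(rng), normal32(rng)
            ref = from_float(float(np.float32(to_float(x))
                                   * np.float32(to_float(y))))
            assert encode(fp_multiply(x, y, RNE)) == encode(ref)

    def test_truncate_within_one_ulp(self):
        rng = random.Random(10)
        for _ in range(2000):
            x, y = normal32(rng), normal32(rng)
            ref = from_float(float(np.float32(to_float(x))
                                   * np.float32(to_float(y))))
            assert ulp_diff(fp_multiply(x, y, TRUNC), ref) <= 1

    def test_fp16_rne_bit_equals_host(self):
        rng = random.Random(11)
        for _ in range(1000):
            x, y = normal16(rng), normal16(rng)
            ref = from_float(float(np.float16(to_float(x))
                                   * np.float16(to_float(y))), FP16)
            assert encode(fp_multiply(x, y, RNE)) == encode(ref)

    def test_overflow_saturates_with_flag(self):
        big = from_float(3e38)
        flags = FpFlags()
        r = fp_multiply(big, big, RNE, flags)
        assert flags.overflow
        assert r.exponent == FP32.exp_max - 1
        assert r.mantissa == (1 << 23) - 1

    def test_underflow_flushes_to_signed_zero(self):
        tiny = from_float(1.5e-38)       # smallest-exponent normal range
        flags = FpFlags()
        r = fp_multiply(tiny, from_float(-1e-12), RNE, flags)
        assert flags.underflow
        assert (r.sign, r.exponent, r.mantissa) == (1, 0, 0)

    def test_special_value_propagation(self):
        inf = decode(0x7F800000)
        nan = decode(0x7FC00000)
        zero = from_float(0.0)
        assert fp_multiply(inf, from_float(2.0), RNE).kind == "inf"
        assert fp_multiply(inf, zero, RNE).kind == "nan"
        assert fp_multiply(nan, from_float(2.0), RNE).kind == "nan"

    def test_monotone_magnitude_in_first_operand(self):
        y = from_float(1.7)
        xs = [from_float(v) for v in np.linspace(0.5, 100.0, 64)]
        prods = [abs(to_float(fp_multiply(x, y, TRUNC))) for x in xs]
        assert all(b >= a for a, b in zip(prods, prods[1:]))


class TestAdd:
    def test_simple_sums(self):
        one = from_float(1.0)
        assert to_float(fp_add(one, one)) == 2.0
        x = from_float(0.3)
        assert encode(fp_add(x, from_float(0.0))) == encode(x)

    def test_exact_cancellation_gives_positive_zero(self):
        x = from_float(2.5)
        neg = FloatBits(1, x.exponent, x.mantissa, FP32)
        r = fp_add(x, neg)
        assert (r.sign, r.exponent, r.mantissa) == (0, 0, 0)

    def test_rne_bit_equals_host_sampled(self):
        rng = random.Random(12)
        for _ in range(2000):
            x = normal32(rng, 60, 190)
            y = normal32(rng, 60, 190)
            with np.errstate(all="ignore"):
                ref = from_float(float(np.float32(to_float(x))
                                       + np.float32(to_float(y))))
            assert encode(fp_add(x, y, RNE)) == encode(ref)

    def test_truncate_within_one_ulp(self):
        rng = random.Random(13)
        for _ in range(1000):
            x = normal32(rng, 60, 190)
            y = normal32(rng, 60, 190)
            with np.errstate(all="ignore"):
                ref = from_float(float(np.float32(to_float(x))
                                       + np.float32(to_float(y))))
            assert ulp_diff(fp_add(x, y, TRUNC), ref) <= 1
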