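"""Unit and property tests for the Vedic multiplier / adder emulation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from vedicnn.bitvec_arith import (
    BitVector,
    PartialProductGrid,
    WorkingBase,
    anurupyena_working_base,
    csa_reduce,
    cscgl_add,
    cutin_multiply,
    multiply_8x8_staged,
    nikhilam_multiply,
    partial_products,
    ut_multiply,
    write_test_vectors,
)


def bv(width, value):
    return BitVector(width, value)


class TestBitVector:
    def test_value_range_enforced(self):
        with pytest.raises(ValueError):
            BitVector(3, 8)
        with pytest.raises(ValueError):
            BitVector(0, 0)

    def test_bits_above_width_read_zero(self):
        x = bv(4, 0b1011)
        assert [x.bit(i) for i in range(6)] == [1, 1, 0, 1, 0, 0]


class TestUtMultiply:
    @pytest.mark.parametrize("a, b, expected", [
        (0b101, 0b011, 15),       # 5 * 3 via column sums
        (0, 0b111, 0),            # annihilator
        (1, 0b110, 6),            # identity, zero-extended
    ])
    def test_examples(self, a, b, expected):
        res = ut_multiply(bv(3, a), bv(3, b))
        assert int(res) == expected
        assert res.width == 6

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ut_multiply(bv(3, 1), bv(4, 1))

    @given(st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=200, derandomize=True)
    def test_matches_integer_multiplication(self, a, b):
        assert int(ut_multiply(bv(8, a), bv(8, b))) == a * b

    def test_partial_product_grid_sums_to_product(self):
        g = partial_products(bv(8, 173), bv(8, 94))
        assert int(g) == 173 * 94


class TestAnurupyena:
    @pytest.mark.parametrize("a, b, base, ratio", [
        (48, 52, 50, 5),
        (98, 97, 100, 1),
        (1, 1, 1, 1),
    ])
    def test_decimal_examples(self, a, b, base, ratio):
        wb = anurupyena_working_base(bv(8, a), bv(8, b), radix=10)
        assert wb.base == base
        assert wb.ratio == ratio

    def test_tie_breaks_to_smaller_base(self):
        # 25 is equidistant from bases 20 and 30
        wb = anurupyena_working_base(bv(8, 25), bv(8, 25), radix=10)
        assert wb.base == 20

    def test_minimises_max_distance_brute_force(self):
        rng = random.Random(5)
        for _ in range(200):
            a, b = rng.randint(1, 4000), rng.randint(1, 4000)
            wb = anurupyena_working_base(bv(16, a), bv(16, b), radix=10)
            got = max(abs(a - wb.base), abs(b - wb.base))
            best = min(
                max(abs(a - m * 10**k), abs(b - m * 10**k))
                for k in range(6) for m in range(1, 10))
            assert got == best

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            anurupyena_working_base(bv(4, 0), bv(4, 3))


class TestNikhilam:
    def test_near_base_below(self):
        wb = WorkingBase(100, 1, 10, 2)
        assert int(nikhilam_multiply(bv(8, 98), bv(8, 97), wb)) == 9506

    def test_excess_over_base(self):
        wb = WorkingBase(10, 1, 10, 1)
        assert int(nikhilam_multiply(bv(8, 12), bv(8, 13), wb)) == 156

    def test_operand_equal_to_base(self):
        wb = WorkingBase(100, 1, 10, 2)
        assert int(nikhilam_multiply(bv(8, 100), bv(8, 37), wb)) == 3700

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            WorkingBase(0, 1, 10, 0)

    @given(st.integers(1, 65535), st.integers(1, 65535))
    @settings(max_examples=300, derandomize=True)
    def test_auto_base_matches_integer_multiplication(self, a, b):
        assert int(nikhilam_multiply(bv(16, a), bv(16, b))) == a * b


class TestCutin:
    def test_rejects_bad_widths(self):
        with pytest.raises(ValueError):
            cutin_multiply(bv(6, 3), bv(6, 3))
        with pytest.raises(ValueError):
            cutin_multiply(bv(8, 3), bv(16, 3))

    def test_single_bit_operands(self):
        for n in (4, 8, 16):
            top = 1 << (n - 1)
            assert int(cutin_multiply(bv(n, top), bv(n, top))) == top * top

    @given(st.integers(0, 2**32 - 1), st.integers(0, 2**32 - 1))
    @settings(max_examples=300, derandomize=True)
    def test_matches_integer_multiplication_32bit(self, a, b):
        assert int(cutin_multiply(bv(32, a), bv(32, b))) == a * b

    @given(st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=200, derandomize=True)
    def test_algorithms_agree(self, a, b):
        """UT, NAS and CUTIN are interchangeable where all are defined."""
        x, y = bv(8, a), bv(8, b)
        ut = int(ut_multiply(x, y))
        cu = int(cutin_multiply(x, y))
        assert ut == cu
        if a > 0 and b > 0:
            assert int(nikhilam_multiply(x, y)) == ut

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=200, derandomize=True)
    def test_commutativity(self, a, b):
        x, y = bv(16, a), bv(16, b)
        assert int(cutin_multiply(x, y)) == int(cutin_multiply(y, x))
        assert int(ut_multiply(x, y)) == int(ut_multiply(y, x))


class TestCsaReduce:
    def test_three_rows(self):
        g = PartialProductGrid(tuple((bv(4, v), 0) for v in (5, 3, 9)))
        pair = csa_reduce(g)
        assert int(pair.sum_vec) + 2 * int(pair.carry_vec) == 17

    def test_single_row_passthrough(self):
        g = PartialProductGrid(((bv(4, 11), 0),))
        pair = csa_reduce(g)
        assert int(pair) == 11 and int(pair.carry_vec) == 0

    def test_all_zero_rows(self):
        g = PartialProductGrid(tuple((bv(4, 0), 0) for _ in range(5)))
        assert int(csa_reduce(g)) == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            csa_reduce(PartialProductGrid(()))

    @given(st.lists(st.integers(0, 2**20), min_size=1, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_sum_preserved_at_every_stage(self, values):
        g = PartialProductGrid(tuple((bv(21, v), 0) for v in values))
        pair, stages = csa_reduce(g, return_stages=True)
        total = sum(values)
        for stage in stages:
            assert sum(stage) == total
        assert int(pair) == total


class TestCscglAdd:
    @pytest.mark.parametrize("a, b, cin, expected", [
        (0, 0, 0, 0),
        (255, 1, 0, 256),     # ripple through every bit position
        (170, 85, 1, 256),
    ])
    def test_examples(self, a, b, cin, expected):
        res = cscgl_add(bv(8, a), bv(8, b), cin)
        assert int(res) == expected
        assert res.width == 9

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cscgl_add(bv(8, 1), bv(4, 1))

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1),
           st.integers(0, 1))
    @settings(max_examples=300, derandomize=True)
    def test_matches_integer_addition_12bit(self, a, b, cin):
        assert int(cscgl_add(bv(12, a), bv(12, b), cin)) == a + b + cin


class TestStaged8x8:
    @pytest.mark.parametrize("a, b", [(255, 255), (16, 16), (0, 200),
                                      (1, 1), (199, 73)])
    def test_examples(self, a, b):
        assert int(multiply_8x8_staged(bv(8, a), bv(8, b))) == a * b

    def test_requires_width_8(self):
        with pytest.raises(ValueError):
            multiply_8x8_staged(bv(4, 3), bv(4, 3))


def test_test_vector_writer(tmp_path):
    path = tmp_path / "vectors.txt"
    n = write_test_vectors(path, "cutin", 16, count=50, seed=3)
    lines = path.read_text().splitlines()
    assert n == len(lines) == 50
    for line in lines:
        a, b, p = (int(tok, 16) for tok in line.split())
        assert a * b == p
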