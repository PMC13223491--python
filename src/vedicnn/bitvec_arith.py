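"""Bit-accurate Vedic multipliers and carry-save/CSCGL adders.

This module emulates, in software, the integer arithmetic units of a
hardware convolution accelerator built from Vedic sutras:

* **UT (Urdhva Tiryagbhyam, "vertical and crosswise")** — all partial-product
  columns are formed simultaneously and summed with explicit carry
  propagation, the classic parallel Vedic multiplier.
* **NAS (Nikhilam with the Anurupyena upasutra)** — multiplication through
  base complements: for operands near a working base ``W = m·B^k`` the
  product is ``(a + b − W)·W + (W − a)(W − b)``, which turns a large
  multiplication into one small complement product plus shifts.
* **CUTIN** — the hybrid: an N×N multiply is decomposed crosswise into four
  N/2×N/2 sub-products; each sub-product is routed to NAS when both
  sub-operands sit close to a working base, otherwise handled by UT/further
  decomposition.  Partial products are reduced carry-save (3:2) and the
  final pair is merged by the CSCGL adder.
* **CSCGL** — a carry-select-style adder decomposed into a Partial Sum Unit
  (half-adder layer), a Carry generating Unit (combinational carry chain,
  no multiplexed duplicate adders), and a Final Sum Unit.

Every operation is an exact integer multiplier/adder: the point of the
emulation is that the *internal structure* mirrors the hardware datapath,
so the layer above (IEEE-754 emulation, quantized convolution) exercises
the same arithmetic the accelerator would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "BitVector",
    "CarrySavePair",
    "PartialProductGrid",
    "WorkingBase",
    "ut_multiply",
    "partial_products",
    "nikhilam_multiply",
    "anurupyena_working_base",
    "cutin_multiply",
    "csa_reduce",
    "cscgl_add",
    "multiply_8x8_staged",
    "write_test_vectors",
    "NAS_CLOSENESS_SHIFT",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitVector:
    """A fixed-width unsigned binary operand.

    Invariant: ``0 <= value < 2**width``; bits at or above ``width`` read 0.
    """

    width: int
    value: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if not (0 <= self.value < (1 << self.width)):
            raise ValueError(
                f"value {self.value} out of range for width {self.width}"
            )

    def bit(self, i: int) -> int:
        if i < 0:
            raise ValueError("bit index must be non-negative")
        return (self.value >> i) & 1

    def __int__(self) -> int:
        return self.value

    def __index__(self) -> int:
        return self.value

    def bits(self) -> Iterator[int]:
        """LSB-first bit iterator over the declared width."""
        return iter(self.bit(i) for i in range(self.width))


@dataclass(frozen=True)
class CarrySavePair:
    """Redundant sum/carry representation of an integer.

    The carry vector is stored *unshifted*; its weight-2 factor lives in the
    invariant ``int(sum_vec) + 2*int(carry_vec) == represented integer``.
    """

    sum_vec: BitVector
    carry_vec: BitVector

    def __int__(self) -> int:
        return int(self.sum_vec) + 2 * int(self.carry_vec)


@dataclass(frozen=True)
class PartialProductGrid:
    """Rows of partial products with per-row left-shift offsets.

    ``sum(int(row) << off for row, off in rows)`` is the exact value the
    grid represents.
    """

    rows: tuple[tuple[BitVector, int], ...]

    def __int__(self) -> int:
        return sum(int(r) << off for r, off in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class WorkingBase:
    """An Anurupyena working base ``m·B^k`` (B the radix: 10 or 2)."""

    base: int
    ratio: int
    radix: int = 10
    power: int = 0

    def __post_init__(self) -> None:
        if self.base <= 0:
            raise ValueError("working base must be positive")
        if self.base != self.ratio * self.radix**self.power:
            raise ValueError(
                f"base {self.base} != ratio {self.ratio} * "
                f"{self.radix}^{self.power}"
            )


# routing threshold for the NAS path inside CUTIN: both sub-operands must be
# within 2**(w - NAS_CLOSENESS_SHIFT) of the working base (w = operand width)
NAS_CLOSENESS_SHIFT = 2


# ---------------------------------------------------------------------------
# integer-level kernels (fast paths; the public ops wrap them in BitVectors)
# ---------------------------------------------------------------------------

def _ut_int(a: int, b: int, n: int) -> int:
    """Urdhva Tiryagbhyam column-sum multiply of two n-bit integers."""
    a_bits = [(a >> i) & 1 for i in range(n)]
    b_bits = [(b >> i) & 1 for i in range(n)]
    result = 0
    carry = 0
    for k in range(2 * n - 1):
        lo = max(0, k - n + 1)
        hi = min(k, n - 1)
        col = carry
        for i in range(lo, hi + 1):
            col += a_bits[i] & b_bits[k - i]
        result |= (col & 1) << k
        carry = col >> 1
    result |= carry << (2 * n - 1)
    return result


def _cscgl_int(a: int, b: int, cin: int, n: int) -> int:
    """CSCGL addition: PSU (half adders), CU (carry chain), FSU (xor merge)."""
    s0 = a ^ b          # PSU partial sums
    c0 = a & b          # PSU partial carries
    # CU: derive the selected carry into each position combinationally
    carries = 0
    c = cin
    for i in range(n):
        carries |= c << i
        c = ((c0 >> i) & 1) | (((s0 >> i) & 1) & c)
    # FSU: merge partial sum with selected carries; c is the carry-out
    return (s0 ^ carries) | (c << n)


def _csa_rows_reduce(rows: list[int]) -> list[list[int]]:
    """3:2 carry-save reduction; returns the list of stages (incl. input)."""
    stages = [list(rows)]
    cur = list(rows)
    while len(cur) > 2:
        nxt: list[int] = []
        i = 0
        while i + 3 <= len(cur):
            x, y, z = cur[i], cur[i + 1], cur[i + 2]
            nxt.append(x ^ y ^ z)
            nxt.append(((x & y) | (y & z) | (x & z)) << 1)
            i += 3
        nxt.extend(cur[i:])
        cur = nxt
        stages.append(list(cur))
    return stages


_NIKHILAM_M_BIN = (1, 3, 5, 7)   # odd scale factors for binary working bases
_NIKHILAM_M_DEC = tuple(range(1, 10))


def _base_candidates(limit: int, radix: int) -> Iterator[int]:
    ms = _NIKHILAM_M_DEC if radix == 10 else _NIKHILAM_M_BIN
    p = 1
    while True:
        for m in ms:
            yield m * p
        if p > 2 * limit:
            return
        p *= radix


_BASE_TABLES: dict[int, tuple[list[int], dict[int, tuple[int, int]], int]] = {}


def _base_table(radix: int, limit: int):
    """Sorted candidate bases m·radix^k up to ``limit`` (cached, extended lazily)."""
    ms = _NIKHILAM_M_DEC if radix == 10 else _NIKHILAM_M_BIN
    table = _BASE_TABLES.get(radix)
    if table is not None and table[2] >= limit:
        return table[0], table[1]
    top = max(limit, 16)
    bases: set[int] = set()
    decomp: dict[int, tuple[int, int]] = {}
    p, k = 1, 0
    while p <= top:
        for m in ms:
            base = m * p
            if base not in decomp or m < decomp[base][0]:
                decomp[base] = (m, k)
            bases.add(base)
        p *= radix
        k += 1
    ordered = sorted(bases)
    _BASE_TABLES[radix] = (ordered, decomp, top)
    return ordered, decomp


def _nearest_working_base(a: int, b: int, radix: int) -> tuple[int, int, int]:
    """(base, ratio, power) minimising max(|a-base|, |b-base|); ties -> smaller.

    max(|a-W|, |b-W|) == |W - (a+b)/2| + |a-b|/2, so the optimum is the
    candidate base nearest the midpoint of the operands.
    """
    from bisect import bisect_left

    lo, hi = min(a, b), max(a, b)
    ordered, decomp = _base_table(radix, 2 * max(hi, 1) * radix)
    twice_mid = a + b
    i = bisect_left(ordered, (twice_mid + 1) // 2)
    best: tuple[int, int] | None = None  # (2*|W - mid|, base)
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(ordered):
            base = ordered[j]
            d = abs(2 * base - twice_mid)
            if best is None or d < best[0] or (d == best[0] and base < best[1]):
                best = (d, base)
    assert best is not None
    base = best[1]
    m, k = decomp[base]
    return base, m, k


def _nikhilam_int(a: int, b: int, base: int, ratio: int, power: int,
                  radix: int) -> int:
    """Complement multiplication about working base ``ratio * radix**power``.

    Identity: a*b == (a + b - W)*W + (W - a)*(W - b).  The complement
    product is a small multiply handled by UT; the left part is scaled by
    the Anurupyena ratio and shifted by the theoretical base.  Deficits
    (operands below base) appear as signed intermediates, emulating the
    digit-borrow bookkeeping of the sutra.
    """
    ca = base - a
    cb = base - b
    left = a - cb  # == b - ca == a + b - W
    # complement product via UT on the magnitudes
    w = max(abs(ca).bit_length(), abs(cb).bit_length(), 1)
    right = _ut_int(abs(ca), abs(cb), w)
    if (ca < 0) ^ (cb < 0):
        right = -right
    # left part: multiply by ratio m (small UT), then shift by B^power
    lw = max(abs(left).bit_length(), ratio.bit_length(), 1)
    scaled = _ut_int(abs(left), ratio, lw)
    if left < 0:
        scaled = -scaled
    return scaled * radix**power + right


_CUTIN_CACHE: dict[tuple[int, int], int] = {}


def _cutin_int(a: int, b: int, n: int) -> int:
    """Hybrid CUTIN multiply of two n-bit integers (n a power of two >= 4)."""
    if n <= 4:
        return _ut_int(a, b, n)
    if n == 8:
        cached = _CUTIN_CACHE.get((a, b))
        if cached is not None:
            return cached
    # NAS dispatch: both operands close to a shared binary working base
    if a > 0 and b > 0:
        base, ratio, power = _nearest_working_base(a, b, 2)
        thr = 1 << (n - NAS_CLOSENESS_SHIFT)
        if abs(a - base) <= thr and abs(b - base) <= thr:
            p = _nikhilam_int(a, b, base, ratio, power, 2)
            if n == 8:
                _CUTIN_CACHE[(a, b)] = p
            return p
    # UT crosswise decomposition into four half-width sub-products
    h = n // 2
    mask = (1 << h) - 1
    al, ah = a & mask, a >> h
    bl, bh = b & mask, b >> h
    p_ll = _cutin_int(al, bl, h)
    p_lh = _cutin_int(al, bh, h)
    p_hl = _cutin_int(ah, bl, h)
    p_hh = _cutin_int(ah, bh, h)
    rows = [p_ll, p_lh << h, p_hl << h, p_hh << n]
    stages = _csa_rows_reduce(rows)
    s, c = stages[-1] if len(stages[-1]) == 2 else (stages[-1][0], 0)
    p = _cscgl_int(s, c, 0, max(s.bit_length(), c.bit_length(), 1))
    if n == 8:
        _CUTIN_CACHE[(a, b)] = p
    return p


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _require_same_width(a: BitVector, b: BitVector) -> None:
    if a.width != b.width:
        raise ValueError(f"width mismatch: {a.width} != {b.width}")


def ut_multiply(a: BitVector, b: BitVector) -> BitVector:
    """Vertical-and-crosswise (UT) multiplication.

    Column sums ``s_k = sum_{i+j=k} a_i b_j`` are formed for every output
    position simultaneously and carries are propagated once across columns,
    rather than accumulating shifted addends sequentially.
    """
    _require_same_width(a, b)
    return BitVector(2 * a.width, _ut_int(a.value, b.value, a.width))


def partial_products(a: BitVector, b: BitVector) -> PartialProductGrid:
    """The UT partial-product grid: row i is ``a AND -bit_i(b)`` at offset i."""
    _require_same_width(a, b)
    rows = tuple(
        (BitVector(a.width, a.value if b.bit(i) else 0), i)
        for i in range(b.width)
    )
    return PartialProductGrid(rows)


def anurupyena_working_base(a: BitVector, b: BitVector,
                            radix: int = 10) -> WorkingBase:
    """Select the working base ``m·B^k`` nearest both operands.

    Minimises ``max(|a - base|, |b - base|)`` over candidate bases; on a tie
    the smaller base wins (deterministic).  ``radix`` is 10 in the decimal
    presentation of the sutra and 2 in the hardware datapath.
    """
    av, bv = int(a), int(b)
    if av <= 0 or bv <= 0:
        raise ValueError("operands must be positive to select a working base")
    base, ratio, power = _nearest_working_base(av, bv, radix)
    return WorkingBase(base=base, ratio=ratio, radix=radix, power=power)


def nikhilam_multiply(a: BitVector, b: BitVector,
                      base: WorkingBase | None = None) -> BitVector:
    """Nikhilam ("all from 9 and the last from 10") complement multiplication.

    With complements ``ca = W - a`` and ``cb = W - b`` about working base W,
    the product is the left part ``(a - cb)`` scaled per Anurupyena plus the
    complement product ``ca·cb`` folded in.  Operands may lie above or below
    the base.  When ``base`` is None it is selected automatically (binary
    radix, matching the datapath).
    """
    if base is None:
        base = anurupyena_working_base(a, b, radix=2)
    if base.base <= 0:
        raise ValueError("working base must be positive")
    p = _nikhilam_int(int(a), int(b), base.base, base.ratio, base.power,
                      base.radix)
    return BitVector(a.width + b.width, p)


def cutin_multiply(a: BitVector, b: BitVector) -> BitVector:
    """CUTIN hybrid multiply: crosswise decomposition + NAS/UT routing.

    N×N is built from four N/2×N/2 sub-products.  A (sub-)product is routed
    to the Nikhilam/Anurupyena complement path when both operands lie within
    ``2**(w-2)`` of a shared working base, else it is decomposed further,
    down to 4-bit UT column-sum blocks.  Partial products are reduced 3:2
    carry-save and the final sum/carry pair is merged by the CSCGL adder.
    """
    _require_same_width(a, b)
    n = a.width
    if n < 4 or (n & (n - 1)) != 0:
        raise ValueError(f"operand width must be a power of two >= 4, got {n}")
    return BitVector(2 * n, _cutin_int(a.value, b.value, n))


def csa_reduce(grid: PartialProductGrid,
               return_stages: bool = False):
    """Carry-save (3:2) reduction of a partial-product grid to a sum/carry pair.

    Full-adder layers compress rows three at a time, saving sums and carries
    without propagating; reduction repeats until two vectors remain.  With
    ``return_stages`` the intermediate row sets are also returned so the
    sum-preservation invariant can be checked stage by stage.
    """
    if len(grid) == 0:
        raise ValueError("cannot reduce an empty partial-product grid")
    rows = [int(r) << off for r, off in grid.rows]
    stages = _csa_rows_reduce(rows)
    final = stages[-1]
    if len(final) == 1:
        s, c = final[0], 0
    else:
        # finishing half-adder layer: x + y == (x ^ y) + 2*(x & y), so the
        # stored (unshifted) carry vector satisfies the pair invariant
        x, y = final
        s, c = x ^ y, x & y
    w = max(s.bit_length(), c.bit_length(), 1)
    pair = CarrySavePair(BitVector(w, s), BitVector(w, c))
    if return_stages:
        return pair, stages
    return pair


def cscgl_add(a: BitVector, b: BitVector, cin: int = 0) -> BitVector:
    """CSCGL addition of two n-bit vectors with carry-in; result is n+1 bits.

    PSU forms per-bit partial sums/carries with half adders; CU derives the
    selected carry into every position from (c0, cin) by a combinational
    chain — no duplicated adders behind a multiplexer; FSU xors the selected
    carries into the partial sum.
    """
    _require_same_width(a, b)
    if cin not in (0, 1):
        raise ValueError("carry-in must be 0 or 1")
    return BitVector(a.width + 1,
                     _cscgl_int(a.value, b.value, cin, a.width))


def multiply_8x8_staged(a: BitVector, b: BitVector) -> BitVector:
    """8×8 multiply from four 4×4 blocks with staged carry insertion.

    The procedure mirrors the 4×4 scheme, starting from a zero pre-carry:
    each stage adds the cross partial products plus the carry nibble of the
    previous stage through the CSCGL adder.
    """
    if a.width != 8 or b.width != 8:
        raise ValueError("multiply_8x8_staged requires 8-bit operands")
    al, ah = a.value & 0xF, a.value >> 4
    bl, bh = b.value & 0xF, b.value >> 4
    q0 = _ut_int(al, bl, 4)   # low block
    q1 = _ut_int(ah, bl, 4)   # cross
    q2 = _ut_int(al, bh, 4)   # cross
    q3 = _ut_int(ah, bh, 4)   # high block
    # stage 1: cross products, zero pre-carry
    mid = _cscgl_int(q1, q2, 0, 8)
    # stage 2: fold in the carry nibble of the low block
    mid = _cscgl_int(mid, q0 >> 4, 0, 9)
    # stage 3: high block plus the carry byte of the middle stage
    high = _cscgl_int(q3, mid >> 4, 0, 8)
    result = (high << 8) | ((mid & 0xF) << 4) | (q0 & 0xF)
    return BitVector(16, result)


def write_test_vectors(path, algo: str, width: int, count: int | None = None,
                       seed: int = 0) -> int:
    """Write ``a_hex b_hex product_hex`` lines for external HDL verification.

    Exhaustive when ``count`` is None and width == 8; otherwise ``count``
    seeded random pairs.  Returns the number of lines written.
    """
    import random

    fns = {
        "ut": ut_multiply,
        "nas": lambda x, y: nikhilam_multiply(x, y, None),
        "cutin": cutin_multiply,
    }
    if algo not in fns:
        raise ValueError(f"unknown algorithm {algo!r}")
    fn = fns[algo]
    digits = (width + 3) // 4
    n = 0
    with open(path, "w") as fh:
        if count is None:
            if width != 8:
                raise ValueError("exhaustive vectors only at width 8")
            pairs = ((x, y) for x in range(256) for y in range(256))
        else:
            rng = random.Random(seed)
            top = (1 << width) - 1
            pairs = ((rng.randint(0, top), rng.randint(0, top))
                     for _ in range(count))
        for x, y in pairs:
            p = fn(BitVector(width, x), BitVector(width, y))
            fh.write(f"{x:0{digits}x} {y:0{digits}x} {int(p):0{2*digits}x}\n")
            n += 1
    return n
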