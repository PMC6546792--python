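"""Binary narrow-sense BCH codes over GF(2^m).

Systematic encoding (info bits first, parity appended) and bounded-distance
decoding via syndromes, Berlekamp–Massey, and Chien search. Shortened codes
are supported by treating the dropped leading information positions as zeros;
an error located in the shortened region marks the block uncorrectable.

Bit strings are plain ``str`` of '0'/'1'. Index 0 of the string is the
highest-degree coefficient of the codeword polynomial.
"""

from __future__ import annotations

import re
from functools import lru_cache

__all__ = ["BCHCode", "BCHDecodeFailure", "GF2m"]

# one primitive polynomial per field order (standard choices)
_PRIMITIVE_POLY = {
    3: 0b1011,
    4: 0b10011,
    5: 0b100101,
    6: 0b1000011,
    7: 0b10001001,
    8: 0b100011101,
    9: 0b1000010001,
    10: 0b10000001001,
}


class BCHDecodeFailure(ValueError):
    """Raised when a received block is outside the decoding radius."""


class GF2m:
    """Log/antilog tables for GF(2^m) with a fixed primitive element."""

    def __init__(self, m: int):
        if m not in _PRIMITIVE_POLY:
            raise ValueError(f"unsupported field GF(2^{m})")
        self.m = m
        self.q = (1 << m) - 1
        poly = _PRIMITIVE_POLY[m]
        self.exp = [0] * (2 * self.q)
        self.log = [0] * (self.q + 1)
        x = 1
        for i in range(self.q):
            self.exp[i] = x
            self.log[x] = i
            x <<= 1
            if x & (1 << m):
                x ^= poly
        for i in range(self.q, 2 * self.q):
            self.exp[i] = self.exp[i - self.q]

    def mul(self, a: int, b: int) -> int:
        if a == 0 or b == 0:
            return 0
        return self.exp[self.log[a] + self.log[b]]

    def inv(self, a: int) -> int:
        if a == 0:
            raise ZeroDivisionError
        return self.exp[self.q - self.log[a]]

    def pow_alpha(self, e: int) -> int:
        return self.exp[e % self.q]


def _poly_mul_gf2(a: int, b: int) -> int:
    """Multiply polynomials over GF(2) packed as ints (bit i = coeff of x^i)."""
    r = 0
    while b:
        if b & 1:
            r ^= a
        a <<= 1
        b >>= 1
    return r


def _minimal_polynomial(field: GF2m, elem_log: int) -> int:
    """Minimal polynomial over GF(2) of alpha^elem_log, packed as an int."""
    # conjugacy class {e, 2e, 4e, ...} mod (2^m - 1)
    q = field.q
    conj = []
    e = elem_log % q
    while e not in conj:
        conj.append(e)
        e = (2 * e) % q
    # product of (x - alpha^c): coefficients in GF(2^m), collapse to GF(2)
    poly = [1]  # coefficients, poly[i] = coeff of x^i, highest degree last
    for c in conj:
        root = field.pow_alpha(c)
        new = [0] * (len(poly) + 1)
        for i, coeff in enumerate(poly):
            new[i + 1] ^= coeff
            new[i] ^= field.mul(coeff, root)
        poly = new
    packed = 0
    for i, coeff in enumerate(poly):
        if coeff not in (0, 1):
            raise AssertionError("minimal polynomial has non-binary coefficient")
        packed |= coeff << i
    return packed


@lru_cache(maxsize=None)
def _generator_polynomial(m: int, t: int) -> int:
    """g(x) = lcm of minimal polynomials of alpha^1 .. alpha^2t."""
    field = GF2m(m)
    seen: set[int] = set()
    g = 1
    for i in range(1, 2 * t + 1):
        mp = _minimal_polynomial(field, i)
        if mp not in seen:
            seen.add(mp)
            g = _poly_mul_gf2(g, mp)
    return g


class BCHCode:
    """A (possibly shortened) binary BCH code with bounded-distance decoding.

    Parameters
    ----------
    m : field degree; natural length n = 2^m - 1.
    t : designed error-correction capability.
    k_short : info bits after shortening (default: full k).
    pad_bits : fixed zero bits appended to the encoded block so that the
        serialized block length is k_short + parity + pad_bits.
    """

    def __init__(self, m: int, t: int, k_short: int | None = None, pad_bits: int = 0):
        self.field = GF2m(m)
        self.m = m
        self.t = t
        self.n = self.field.q
        g = _generator_polynomial(m, t)
        self.generator = g
        self.n_parity = g.bit_length() - 1
        self.k = self.n - self.n_parity
        if k_short is None:
            k_short = self.k
        if not 0 < k_short <= self.k:
            raise ValueError(f"k_short={k_short} out of range for k={self.k}")
        self.k_short = k_short
        self.pad_bits = pad_bits
        self.block_bits = self.k_short + self.n_parity + pad_bits

    # -- spec strings ------------------------------------------------------
    _SPEC_RES = [
        # bch(63,36,t=5)
        (re.compile(r"^bch\((\d+),(\d+),t=(\d+)\)$"), "plain"),
        # bch-short(1023,1013,t=1)->(33,23)
        (
            re.compile(r"^bch-short\((\d+),(\d+),t=(\d+)\)->\((\d+),(\d+)\)$"),
            "short",
        ),
        # bch-pad(127,57,t=11)+1
        (re.compile(r"^bch-pad\((\d+),(\d+),t=(\d+)\)\+(\d+)$"), "pad"),
    ]

    @classmethod
    def from_spec(cls, spec: str, omega: int | None = None, B: int | None = None):
        """Build a code from a spec string; returns None for 'none'."""
        if spec == "none":
            return None
        for regex, kind in cls._SPEC_RES:
            mobj = regex.match(spec)
            if not mobj:
                continue
            nums = [int(x) for x in mobj.groups()]
            n = nums[0]
            m = n.bit_length()
            if (1 << m) - 1 != n:
                raise ValueError(f"n={n} is not 2^m - 1")
            t = nums[2]
            if kind == "plain":
                code = cls(m, t)
            elif kind == "short":
                _, k_full = nums[3], nums[4]
                code = cls(m, t, k_short=nums[4])
            else:  # pad
                code = cls(m, t, pad_bits=nums[3])
            if nums[1] != code.k:
                raise ValueError(f"spec k={nums[1]} but code has k={code.k}")
            if omega is not None and code.k_short != omega:
                raise ValueError(f"profile omega={omega} != code info bits {code.k_short}")
            if B is not None and code.block_bits != B:
                raise ValueError(f"profile B={B} != code block bits {code.block_bits}")
            return code
        raise ValueError(f"unsupported ECC spec {spec!r}")

    # -- encode ------------------------------------------------------------
    def encode(self, info_bits: str) -> str:
        if len(info_bits) != self.k_short:
            raise ValueError(f"expected {self.k_short} info bits, got {len(info_bits)}")
        msg = int(info_bits, 2) if info_bits else 0
        # systematic: c(x) = m(x) x^{n-k} + (m(x) x^{n-k} mod g(x))
        shifted = msg << self.n_parity
        rem = shifted
        g = self.generator
        gdeg = self.n_parity
        while rem.bit_length() - 1 >= gdeg and rem:
            rem ^= g << (rem.bit_length() - 1 - gdeg)
        parity = format(rem, f"0{self.n_parity}b") if self.n_parity else ""
        return info_bits + parity + "0" * self.pad_bits

    # -- decode ------------------------------------------------------------
    def decode(self, block_bits: str) -> tuple[str, int]:
        """Return (info bits, number of corrected bit errors).

        Raises BCHDecodeFailure when more than t errors are detected
        (including any error placed in the shortened or padded region).
        """
        if len(block_bits) != self.block_bits:
            raise ValueError(f"expected {self.block_bits} bits, got {len(block_bits)}")
        if self.pad_bits:
            if set(block_bits[-self.pad_bits :]) - {"0"}:
                raise BCHDecodeFailure("non-zero padding bits")
            block_bits = block_bits[: -self.pad_bits]
        short_len = self.k_short + self.n_parity
        # codeword poly degree n-1 .. 0; bit string index i -> degree short_len-1-i
        received = [int(b) for b in block_bits]
        field = self.field
        syndromes = []
        for j in range(1, 2 * self.t + 1):
            s = 0
            for i, bit in enumerate(received):
                if bit:
                    s ^= field.pow_alpha(j * (short_len - 1 - i))
            syndromes.append(s)
        if not any(syndromes):
            return block_bits[: self.k_short], 0
        sigma = self._berlekamp_massey(syndromes)
        n_err = len(sigma) - 1
        if n_err > self.t:
            raise BCHDecodeFailure("error locator degree exceeds t")
        positions = self._chien_search(sigma, short_len)
        if len(positions) != n_err:
            raise BCHDecodeFailure("error locator has wrong number of roots in range")
        corrected = received[:]
        for deg in positions:
            corrected[short_len - 1 - deg] ^= 1
        # re-check syndromes on the corrected word to reject miscorrections
        for j in range(1, 2 * self.t + 1):
            s = 0
            for i, bit in enumerate(corrected):
                if bit:
                    s ^= field.pow_alpha(j * (short_len - 1 - i))
            if s:
                raise BCHDecodeFailure("correction did not cancel syndromes")
        info = "".join(str(b) for b in corrected[: self.k_short])
        return info, n_err

    def _berlekamp_massey(self, syndromes: list[int]) -> list[int]:
        """Error locator sigma(x) as coefficient list [1, s1, s2, ...]."""
        field = self.field
        C = [1]
        B = [1]
        L = 0
        mshift = 1
        b = 1
        for n, s in enumerate(syndromes):
            d = s
            for i in range(1, L + 1):
                if i < len(C):
                    d ^= field.mul(C[i], syndromes[n - i])
            if d == 0:
                mshift += 1
            elif 2 * L <= n:
                T = C[:]
                coef = field.mul(d, field.inv(b))
                C = C + [0] * max(0, len(B) + mshift - len(C))
                for i, bb in enumerate(B):
                    C[i + mshift] ^= field.mul(coef, bb)
                L = n + 1 - L
                B = T
                b = d
                mshift = 1
            else:
                coef = field.mul(d, field.inv(b))
                C = C + [0] * max(0, len(B) + mshift - len(C))
                for i, bb in enumerate(B):
                    C[i + mshift] ^= field.mul(coef, bb)
                mshift += 1
        while len(C) > 1 and C[-1] == 0:
            C.pop()
        return C

    def _chien_search(self, sigma: list[int], short_len: int) -> list[int]:
        """Degrees (within the shortened word) of located error positions."""
        field = self.field
        positions = []
        for deg in range(short_len):
            # error at position with weight alpha^deg: root at alpha^{-deg}
            x = field.pow_alpha(-deg % field.q)
            acc = 0
            xp = 1
            for c in sigma:
                acc ^= field.mul(c, xp)
                xp = field.mul(xp, x)
            if acc == 0:
                positions.append(deg)
        return positions
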