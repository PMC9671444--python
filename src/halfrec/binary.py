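"""Binary-decomposition machinery.

Every closed formula in this package is expressed in the index language of the
binary decomposition of n: the bit positions ``q_1(n) < ... < q_s(n)`` with
``n = sum(2**q_j)``, the binary weight ``s_n``, and the suffix sums
``M_i(n) = sum_{j>=i} 2**q_j(n)`` (n with its ``i-1`` lowest set bits cleared).

Conventions used throughout: ``q_0(n) = 0``, ``M_0(n) = n + 1`` and
``M_{s+1}(n) = 0``.  Indexing of ``q`` and ``M`` is 1-based to match the
standard notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache


@dataclass(frozen=True)
class BinaryDecomposition:
    """Bit positions, binary weight and suffix sums of a positive integer.

    Attributes
    ----------
    n : the decomposed integer, ``n >= 1``.
    s : binary weight (number of set bits).
    q : tuple of the ``s`` bit positions, strictly increasing; ``q[j-1]`` is
        the 1-based ``q_j(n)``.
    M : tuple of length ``s + 2`` holding ``M_0 .. M_{s+1}`` so that
        ``M[i]`` is the 1-based ``M_i(n)``; ``M[0] = n + 1``, ``M[s+1] = 0``.
    """

    n: int
    s: int
    q: tuple[int, ...]
    M: tuple[int, ...]

    def q_at(self, i: int) -> int:
        """1-based accessor for ``q_i(n)``; ``q_at(0) == 0`` by convention."""
        if i == 0:
            return 0
        if not 1 <= i <= self.s:
            raise IndexError(f"q_{i} undefined for s_n = {self.s}")
        return self.q[i - 1]

    def M_at(self, i: int) -> int:
        """1-based accessor for ``M_i(n)``; indices 0 and s+1 return the
        conventional values ``n + 1`` and ``0``."""
        if not 0 <= i <= self.s + 1:
            raise IndexError(f"M_{i} undefined for s_n = {self.s}")
        return self.M[i]

    @property
    def top(self) -> int:
        """``q_{s_n}(n) = floor(log2(n))``, the highest set bit position."""
        return self.q[-1]


@lru_cache(maxsize=None)
def decompose(n: int) -> BinaryDecomposition:
    """Binary decomposition of ``n >= 1``."""
    if n < 1:
        raise ValueError(f"decompose requires n >= 1, got {n}")
    q = tuple(i for i in range(n.bit_length()) if n >> i & 1)
    s = len(q)
    # suffix sums: M_i = n with the i-1 lowest set bits cleared
    M = [n + 1]
    acc = n
    for pos in q:
        M.append(acc)
        acc -= 1 << pos
    M.append(0)
    return BinaryDecomposition(n=n, s=s, q=q, M=tuple(M))


def shift_decomposition(n: int) -> BinaryDecomposition:
    """Decomposition of ``2n`` from that of ``n``: s is preserved and every
    bit position shifts up by one."""
    bd = decompose(n)
    q = tuple(p + 1 for p in bd.q)
    M = (2 * n + 1,) + tuple(2 * m for m in bd.M[1:])
    return BinaryDecomposition(n=2 * n, s=bd.s, q=q, M=M)


def phi_compose(bits: tuple[int, ...], n: int) -> int:
    """Iterated floor/ceiling halving, evaluated in closed form.

    ``bits`` is the sequence ``b_m ... b_0`` (most significant first); bit 0
    selects floor-half, bit 1 ceiling-half, applied right to left.  By the
    rounding composition identity the result equals
    ``floor((n + sum b_i 2**i) / 2**(m+1))``.
    """
    if not bits:
        raise ValueError("phi_compose requires a non-empty bit sequence")
    if any(b not in (0, 1) for b in bits):
        raise ValueError("bits must be 0 or 1")
    m = len(bits) - 1
    offset = sum(b << (m - pos) for pos, b in enumerate(bits))
    return (n + offset) >> (m + 1)


def phi_iterated(bits: tuple[int, ...], n: int) -> int:
    """Reference evaluation of :func:`phi_compose` by literal iteration."""
    if not bits:
        raise ValueError("phi_iterated requires a non-empty bit sequence")
    x = n
    for b in reversed(bits):
        x = (x + b) // 2  # b=0: floor(x/2); b=1: ceil(x/2)
    return x
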