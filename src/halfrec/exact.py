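"""Exact rational arithmetic substrate: Bernoulli numbers and polynomials,
the geometric-type double sequence T(d, n, x), and Faulhaber power sums.

Everything here is computed over ``fractions.Fraction``.  The case dispatch of
the closed-form solver tests exact equalities such as ``a == 2**(t + l)``,
which would be ill-posed in floating point, so no float ever enters the core.

The convention ``0**0 == 1`` is applied globally (see :func:`ipow`).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

__all__ = [
    "Rational",
    "as_fraction",
    "ipow",
    "bernoulli",
    "bernoulli_poly",
    "T",
    "faulhaber",
    "log2_exact",
]

Rational = Fraction

_bernoulli_table: list[Fraction] = [Fraction(1)]


def as_fraction(value) -> Fraction:
    """Coerce an int, Fraction, or ``"p/q"`` string to an exact Fraction.

    Floats are converted to their exact binary value (so 0.1 != 1/10); pass
    strings for decimal rationals.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise TypeError("booleans are not rational scalars")
    if isinstance(value, (int, str)):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as an exact rational")


def ipow(x, e: int):
    """``x**e`` with the convention ``0**0 == 1`` (also used for ``M_{s+1}**0``)."""
    if e == 0:
        return Fraction(1)
    return Fraction(x) ** e


def bernoulli(m: int) -> Fraction:
    """m-th Bernoulli number of the first kind (``B_1 = -1/2``).

    Defined by ``B_0 = 1`` and ``sum_{k=0}^{m} C(m+1, k) B_k = 0`` for m >= 1;
    the table is grown on demand and memoized.
    """
    if m < 0:
        raise ValueError("Bernoulli numbers need m >= 0")
    while len(_bernoulli_table) <= m:
        j = len(_bernoulli_table)
        # solve sum_{k=0}^{j} C(j+1,k) B_k = 0 for B_j
        acc = sum(comb(j + 1, k) * _bernoulli_table[k] for k in range(j))
        _bernoulli_table.append(Fraction(-acc, j + 1))
    return _bernoulli_table[m]


def bernoulli_poly(m: int, x) -> Fraction:
    """Bernoulli polynomial ``B_m(x) = sum_k C(m,k) B_k x^(m-k)``."""
    xf = as_fraction(x)
    return sum(
        (comb(m, k) * bernoulli(k) * ipow(xf, m - k) for k in range(m + 1)),
        Fraction(0),
    )


def T(d: int, n: int, x) -> Fraction:
    """``T(d, n, x) = sum_{k=0}^{n-1} k^d x^k`` with ``0**0 == 1``.

    For d in {0, 1} the closed forms are used (branching on x == 1); d >= 2
    falls back to direct summation.  ``T(d, 0, x) = 0`` (empty sum);
    x = 0 is rejected.
    """
    xf = as_fraction(x)
    if xf == 0:
        raise ValueError("T(d, n, x) requires x != 0")
    if n < 0:
        raise ValueError("T(d, n, x) requires n >= 0")
    if n == 0:
        return Fraction(0)
    if d == 0:
        if xf == 1:
            return Fraction(n)
        return (ipow(xf, n) - 1) / (xf - 1)
    if d == 1:
        if xf == 1:
            return Fraction(comb(n, 2))
        xn = ipow(xf, n)
        return (n * xn * (xf - 1) - xf * (xn - 1)) / (xf - 1) ** 2
    return sum((ipow(Fraction(k), d) * ipow(xf, k) for k in range(n)), Fraction(0))


def faulhaber(d: int, n: int) -> Fraction:
    """``sum_{k=1}^{n-1} k^d`` via the Bernoulli expansion.

    Uses ``(1/(d+1)) (sum_{j=0}^{d+1} C(d+1,j) B_j n^(d+1-j) + (-1)^d B_{d+1})``.
    """
    if d < 0 or n < 1:
        raise ValueError("faulhaber needs d >= 0 and n >= 1")
    nf = Fraction(n)
    acc = sum(
        (comb(d + 1, j) * bernoulli(j) * ipow(nf, d + 1 - j) for j in range(d + 2)),
        Fraction(0),
    )
    acc += (-1) ** d * bernoulli(d + 1)
    return acc / (d + 1)


def log2_exact(a) -> int | None:
    """Return integer k with ``a == 2**k`` if the rational a is an exact power
    of two, else None (in particular for a <= 0)."""
    af = as_fraction(a)
    if af <= 0:
        return None
    num, den = af.numerator, af.denominator
    if num & (num - 1) or den & (den - 1):
        return None
    return num.bit_length() - den.bit_length()
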