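"""Auxiliary binary-decomposition sums feeding the closed-form solver.

The closed solution of the halving recurrence is assembled from the sums

* ``S_n^(d,m) = sum_{j=1}^{s_n - 1} q_j(n)^d (a 2^-m)^{q_j(n)} M_{j+1}(n)^m``
  (inner sum over all but the highest set bit of n),
* ``alpha_n^(d,m)(a) = sum_{k=1}^{n-1} S_k^(d,m)`` (their running total), and
* ``gamma_l(d,p,m) = sum_{k=1}^{2^l - 1} sum_{i=1}^{s_k} q_i^d (a 2^-m)^{q_i}
  M_{i+1}(k)^p`` (note: inner index runs to ``s_k``, one step further than S).

Each sum has two independent code paths: the literal definition (the oracle)
and a finite closed form whose index ranges are bounded by ``log2(n)`` and the
polynomial degree.  The test suite diffs them exactly.  All arithmetic is
``Fraction``; ``0**0 == 1`` throughout.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

from .binary import decompose
from .exact import T, as_fraction, bernoulli, bernoulli_poly, ipow, log2_exact

__all__ = [
    "S_term",
    "alpha_bruteforce",
    "alpha_closed",
    "alpha00_special",
    "alpha10_special",
    "gamma_bruteforce",
    "gamma_closed",
    "gamma_p0",
    "y_closed",
    "y_delta_sum_direct",
]


def binom(n: int, k: int) -> int:
    """Binomial coefficient, zero outside ``0 <= k <= n``."""
    if k < 0 or k > n:
        return 0
    return comb(n, k)


def S_term(n: int, d: int, m: int, a) -> Fraction:
    """``S_n^(d,m)``: single-n inner sum over the non-leading bits of n.

    Empty (zero) when ``s_n == 1``.
    """
    af = as_fraction(a)
    bd = decompose(n)
    base = af / 2**m
    acc = Fraction(0)
    for j in range(1, bd.s):
        acc += ipow(bd.q_at(j), d) * ipow(base, bd.q_at(j)) * ipow(bd.M_at(j + 1), m)
    return acc


def alpha_bruteforce(n: int, d: int, m: int, a) -> Fraction:
    """Definitional ``alpha_n^(d,m)(a) = sum_{k=1}^{n-1} S_k^(d,m)``.

    Valid for any d >= 0; serves as the oracle for :func:`alpha_closed`.
    """
    if n < 1:
        raise ValueError("alpha needs n >= 1")
    return sum((S_term(k, d, m, a) for k in range(1, n)), Fraction(0))


@lru_cache(maxsize=None)
def alpha_closed(n: int, d: int, m: int, a) -> Fraction:
    """Closed form of ``alpha_n^(d,m)(a)`` for d in {0, 1}.

    Three parts: a Bernoulli/T double sum over the set bits of n, a middle sum
    over all but the highest bit, and a ``-T(d, q_s, 2a)`` correction that is
    present only when m == 0.
    """
    if d not in (0, 1):
        raise ValueError("closed form available only for d in {0, 1}")
    if n < 1:
        raise ValueError("alpha needs n >= 1")
    af = as_fraction(a)
    if af == 0:
        raise ValueError("alpha needs a != 0")
    bd = decompose(n)
    total = Fraction(0)
    for i in range(1, bd.s + 1):
        qi, qim1, Mi = bd.q_at(i), bd.q_at(i - 1), bd.M_at(i)
        for j in range(m + 1):
            x = af * Fraction(2) ** (j - m)
            total += (
                comb(m + 1, j)
                * bernoulli(j)
                * 2**j
                * ipow(Mi, m + 1 - j)
                * (T(d, qi, x) - T(d, qim1, x))
            )
    total /= 2 * (m + 1)
    base = af / 2**m
    for i in range(1, bd.s):
        total += (
            ipow(bd.q_at(i), d)
            * ipow(base, bd.q_at(i))
            * (n - bd.M_at(i))
            * ipow(bd.M_at(i + 1), m)
        )
    if m == 0:
        total -= T(d, bd.top, 2 * af)
    return total


def alpha00_special(n: int, a) -> Fraction:
    """Reduced closed forms of ``alpha_n^(0,0)(a)`` (three branches on a)."""
    af = as_fraction(a)
    bd = decompose(n)
    s, qs = bd.s, bd.top
    if af == 1:
        return (
            (s - 1) * Fraction(n)
            + sum(
                Fraction(2) ** (bd.q_at(i) - 1) * (bd.q_at(i) - 2 * i)
                for i in range(1, s + 1)
            )
            + 1
        )
    if af == Fraction(1, 2):
        return (
            Fraction(n - s - qs)
            + sum(
                Fraction(2) ** (-bd.q_at(j)) * (n - bd.M_at(j))
                for j in range(1, s)
            )
        )
    two_a = 2 * af
    return (
        sum(ipow(af, bd.q_at(j)) * (n - bd.M_at(j)) for j in range(1, s))
        + (sum(ipow(two_a, bd.q_at(j)) for j in range(1, s + 1)) - n)
        / (2 * (af - 1))
        - (ipow(two_a, qs) - 1) / (two_a - 1)
    )


def alpha10_special(n: int, a) -> Fraction:
    """Reduced closed form of ``alpha_n^(1,0)(a)`` via the bit-sum lemma."""
    af = as_fraction(a)
    bd = decompose(n)
    return (
        sum(
            Fraction(2) ** (bd.q_at(i) - 1) * T(1, bd.q_at(i), af)
            for i in range(1, bd.s + 1)
        )
        + sum(
            bd.q_at(i) * ipow(af, bd.q_at(i)) * (n - bd.M_at(i))
            for i in range(1, bd.s)
        )
        - T(1, bd.top, 2 * af)
    )


def gamma_bruteforce(l: int, d: int, p: int, m: int, a) -> Fraction:
    """Literal double sum defining ``gamma_l(d,p,m)``.

    The inner index runs over *all* set bits (up to ``s_k``), so the last term
    involves ``M_{s_k+1} = 0`` and the ``0**0 == 1`` convention when p == 0.
    """
    af = as_fraction(a)
    base = af / 2**m
    acc = Fraction(0)
    for k in range(1, 2**l):
        bd = decompose(k)
        for i in range(1, bd.s + 1):
            acc += ipow(bd.q_at(i), d) * ipow(base, bd.q_at(i)) * ipow(bd.M_at(i + 1), p)
    return acc


def gamma_p0(l: int, d: int, m: int, a) -> Fraction:
    """``gamma_l(d,0,m) = 2^(l-1) T(d, l, a 2^-m)`` (the p == 0 reduction)."""
    if l == 0:
        return Fraction(0)
    af = as_fraction(a)
    return Fraction(2) ** (l - 1) * T(d, l, af / 2**m)


def gamma_closed(l: int, d: int, p: int, m: int, a) -> Fraction:
    """Bernoulli-polynomial closed form of ``gamma_l(d,p,m)``, valid for p < m."""
    if p >= m:
        raise ValueError("gamma closed form requires p < m")
    if l == 0:
        return Fraction(0)
    af = as_fraction(a)
    pref = ipow(af, l - 1) * Fraction(2) ** (-(m - 1) * (l - 1) + p * l) / (p + 1)
    ratio = Fraction(2) ** (m - p - 1) / af
    acc = Fraction(0)
    bp1 = bernoulli(p + 1)
    for tt in range(1, l):
        acc += (
            ipow(l - tt - 1, d)
            * ipow(ratio, tt)
            * (bernoulli_poly(p + 1, Fraction(2) ** tt) - bp1)
        )
    total = pref * acc
    if p == 0:
        total += ipow(af * Fraction(2) ** (-(m - 1)), l - 1) * ipow(l - 1, d)
    return total


def y_delta_sum_direct(k: int, e: int) -> Fraction:
    """``sum_{j=0}^{s_k - 1} M_{j+1}(k)^e (q_{j+1}(k) - q_j(k))`` evaluated
    literally (the raw telescoping form of the difference formula)."""
    bd = decompose(k)
    return sum(
        (
            ipow(bd.M_at(j + 1), e) * (bd.q_at(j + 1) - bd.q_at(j))
            for j in range(bd.s)
        ),
        Fraction(0),
    )


def y_closed(n: int, r: int, t: int, a) -> Fraction:
    """Closed form for the first difference ``x_n^(r,t) - x_{n-1}^(r,t)``.

    Built from the S-sums of ``n - 1``; in the power-of-two branch the
    telescoping sum is expanded into ``S^(1,i)`` terms.
    """
    if n < 2:
        raise ValueError("y is defined for n >= 2")
    af = as_fraction(a)
    if af == 0:
        raise ValueError("a must be nonzero")
    k = n - 1
    bd = decompose(k)
    qs = bd.top
    ell = log2_exact(af)
    ell = ell - t if ell is not None else None
    delta_ell = ell is not None and r > 0 and 0 <= ell <= r - 1

    total = ipow(af, qs)
    for l in range(r):
        if ell is not None and l == ell:
            continue
        total += Fraction(comb(r, l)) / (2 ** (t + l) - af) * (
            ipow(Fraction(k), t + l) - ipow(af, qs)
        )
    for i in range(r + t):
        coef = Fraction(binom(r + t, i), 2**i) - 2 * Fraction(binom(r, i - t), 2**i)
        for l in range(max(0, i - t + 1), r):
            if ell is not None and l == ell:
                continue
            coef -= Fraction(comb(r, l) * binom(t + l, i)) / (2 ** (t + l) - af)
        if coef:
            total += coef * S_term(k, 0, i, af)
    if delta_ell:
        inner = ipow(af, qs) * qs
        for i in range(t + ell):
            inner += comb(t + ell, i) * S_term(k, 1, i, af)
        total += Fraction(comb(r, ell)) / af * inner
    return total
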