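"""Exact closed-form solver for divide-and-conquer halving recurrences.

Solves ``x_n = a x_{ceil(n/2)} + a x_{floor(n/2)} + P(ceil(n/2), floor(n/2))``
with an arbitrary rational coefficient ``a != 0``, a bivariate polynomial toll
``P`` and initial value ``x_1``, in closed form: the answer is a finite sum
over the set bits of n whose index ranges are bounded by ``log2(n)`` and the
toll degree.  By linearity everything reduces to the monomial solutions
``x_n^(r,t)(a)`` (toll ``ceil^r * floor^t``, zero initial value) plus a
homogeneous term proportional to ``x_1``.

The general monomial formula branches on whether ``a`` is an exact power of
two ``2^(t+l)``: when the exponent offset ``l = log2(a) - t`` is an integer in
``{0, ..., r-1}`` certain denominators ``2^(t+l) - a`` vanish, the offending
indices are excluded from the sums and a compensating term (involving the
``alpha^(1,i)`` sums) appears.  :func:`x_monomial` implements the single
general formula; :func:`x_monomial_cased` dispatches to the nine algebraic
specializations, and :func:`oracle_solve` evaluates the recurrence directly by
memoized recursion as the ground truth.  All three agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

from .alphas import alpha_closed, binom
from .binary import decompose
from .exact import T, as_fraction, bernoulli, ipow, log2_exact

__all__ = [
    "TollPolynomial",
    "RecurrenceSpec",
    "CaseProfile",
    "case_profile",
    "x_monomial",
    "x_monomial_cased",
    "homogeneous",
    "solve",
    "oracle_solve",
    "oracle_x_monomial",
    "toll_from_univariate",
    "alternating_toll_expand",
    "stephan_transform",
    "vanishing_check",
]


class TollPolynomial:
    """Sparse bivariate toll polynomial ``P(x, y) = sum b_{r,t} x^r y^t``.

    ``x`` stands for ``ceil(n/2)`` and ``y`` for ``floor(n/2)``.  Zero
    coefficients are dropped on construction; coefficients are exact rationals.
    """

    __slots__ = ("coeffs",)

    def __init__(self, coeffs=None):
        table = {}
        for (r, t), b in dict(coeffs or {}).items():
            if r < 0 or t < 0:
                raise ValueError("toll exponents must be non-negative")
            bf = as_fraction(b)
            if bf:
                table[(int(r), int(t))] = bf
        self.coeffs = table

    @property
    def degree(self) -> int:
        """Total degree ``max(r + t)``; -1 for the zero polynomial."""
        return max((r + t for r, t in self.coeffs), default=-1)

    def __call__(self, x, y) -> Fraction:
        return sum(
            (b * ipow(as_fraction(x), r) * ipow(as_fraction(y), t)
             for (r, t), b in self.coeffs.items()),
            Fraction(0),
        )

    def __add__(self, other: "TollPolynomial") -> "TollPolynomial":
        table = dict(self.coeffs)
        for key, b in other.coeffs.items():
            table[key] = table.get(key, Fraction(0)) + b
        return TollPolynomial(table)

    def scaled(self, c) -> "TollPolynomial":
        cf = as_fraction(c)
        return TollPolynomial({k: cf * b for k, b in self.coeffs.items()})

    def __eq__(self, other):
        return isinstance(other, TollPolynomial) and self.coeffs == other.coeffs

    def __repr__(self):
        terms = ", ".join(f"({r},{t}): {b}" for (r, t), b in sorted(self.coeffs.items()))
        return f"TollPolynomial({{{terms}}})"


@dataclass(frozen=True)
class RecurrenceSpec:
    """One halving-recurrence instance: coefficient a, toll polynomial, x_1."""

    a: Fraction
    toll: TollPolynomial
    x1: Fraction = Fraction(0)

    def __post_init__(self):
        object.__setattr__(self, "a", as_fraction(self.a))
        object.__setattr__(self, "x1", as_fraction(self.x1))
        if self.a == 0:
            raise ValueError("the recurrence coefficient a must be nonzero")

    @classmethod
    def from_json_dict(cls, data: dict) -> "RecurrenceSpec":
        toll = TollPolynomial(
            {(int(r), int(t)): as_fraction(b) for r, t, b in data.get("toll", [])}
        )
        return cls(a=as_fraction(data["a"]), toll=toll, x1=as_fraction(data.get("x1", 0)))

    def to_json_dict(self) -> dict:
        return {
            "a": _fmt(self.a),
            "x1": _fmt(self.x1),
            "toll": [[r, t, _fmt(b)] for (r, t), b in sorted(self.toll.coeffs.items())],
        }


def _fmt(x: Fraction) -> str | int:
    return x.numerator if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


@dataclass(frozen=True)
class CaseProfile:
    """Resolved special-case flags for one monomial instance (r, t, a)."""

    r: int
    t: int
    a: Fraction
    ell: int | None          # log2(a) - t when a is an exact power of two
    delta_ell: int           # 1 iff r > 0 and ell in {0, ..., r-1}
    delta_rt: int            # 1 iff r > 0, t == 0 and a != 1
    which_case: str          # one of a, b1..b4, c1..c4


def case_profile(r: int, t: int, a) -> CaseProfile:
    """Resolve which branch of the closed solution applies to (r, t, a)."""
    af = as_fraction(a)
    if af == 0:
        raise ValueError("a must be nonzero")
    if r < 0 or t < 0:
        raise ValueError("r and t must be non-negative")
    k = log2_exact(af)
    ell = None if k is None else k - t
    delta_ell = int(ell is not None and r > 0 and 0 <= ell <= r - 1)
    delta_rt = int(r > 0 and t == 0 and af != 1)
    if r == 0:
        case = "a"
    elif t == 0:
        if af == Fraction(1, 2):
            case = "b1"
        elif af == 1:
            case = "b2"
        elif ell is not None and 1 <= ell <= r - 1:
            case = "b4"
        else:
            case = "b3"
    else:
        if af == Fraction(1, 2):
            case = "c1"
        elif af == 1:
            case = "c2"
        elif ell is not None and 0 <= ell <= r - 1:
            case = "c4"
        else:
            case = "c3"
    return CaseProfile(r, t, af, ell, delta_ell, delta_rt, case)


def _core0(n: int, qs: int, a: Fraction) -> Fraction:
    """``T(0, q_s, 2a) + n a^q_s - (2a)^q_s`` (the sum of a^{q_{s_k}} over k < n)."""
    return T(0, qs, 2 * a) + n * ipow(a, qs) - ipow(2 * a, qs)


def _core1(n: int, qs: int, a: Fraction) -> Fraction:
    """``T(1, q_s, 2a) + n q_s a^q_s - q_s (2a)^q_s``."""
    return T(1, qs, 2 * a) + n * qs * ipow(a, qs) - qs * ipow(2 * a, qs)


@lru_cache(maxsize=None)
def x_monomial(n: int, r: int, t: int, a) -> Fraction:
    """Closed-form ``x_n^(r,t)(a)``: solution of the monomial recurrence
    ``x_n = a x_ceil + a x_floor + ceil(n/2)^r floor(n/2)^t`` with ``x_1 = 0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prof = case_profile(r, t, a)
    if n == 1:
        return Fraction(0)
    af, ell = prof.a, prof.ell
    d = r + t
    qs = decompose(n).top
    total = Fraction(0)

    # polynomial-in-n part
    for k in range(1, d + 1):
        coef = Fraction(0)
        for i in range(k, d + 1):
            if ell is not None and i == t + ell + 1:
                continue
            c1 = binom(r, i - t - 1)
            if not c1:
                continue
            coef += Fraction(c1 * comb(i, k)) * bernoulli(i - k) / (
                i * (2 ** (i - 1) - af)
            )
        if coef:
            total += coef * ipow(Fraction(n), k)

    if prof.delta_rt:
        total += 1 / (af - 1)

    lsum = Fraction(0)
    for l in range(r):
        if ell is not None and l == ell:
            continue
        lsum += Fraction(comb(r, l)) / (2 ** (t + l) - af)
    total += (1 - lsum) * _core0(n, qs, af)

    for i in range(d):
        coef = Fraction(binom(d, i), 2**i) - 2 * Fraction(binom(r, i - t), 2**i)
        for l in range(max(0, i - t + 1), r):
            if ell is not None and l == ell:
                continue
            coef -= Fraction(comb(r, l) * binom(t + l, i)) / (2 ** (t + l) - af)
        if coef:
            total += coef * alpha_closed(n, 0, i, af)

    if prof.delta_ell:
        inner = _core1(n, qs, af)
        for i in range(t + ell):
            inner += comb(t + ell, i) * alpha_closed(n, 1, i, af)
        total += Fraction(comb(r, ell)) / af * inner
    return total


def x_monomial_cased(n: int, r: int, t: int, a) -> Fraction:
    """``x_n^(r,t)(a)`` via the nine algebraic specializations of the general
    formula (dispatch on :func:`case_profile`); agrees with :func:`x_monomial`
    everywhere."""
    if n < 1:
        raise ValueError("n must be >= 1")
    prof = case_profile(r, t, a)
    if n == 1:
        return Fraction(0)
    af, ell = prof.a, prof.ell
    qs = decompose(n).top
    nf = Fraction(n)
    d = r + t
    a0 = lambda i: alpha_closed(n, 0, i, af)  # noqa: E731
    a1 = lambda i: alpha_closed(n, 1, i, af)  # noqa: E731

    if prof.which_case == "a":
        return (
            sum(
                (Fraction(comb(t, i), 2**i) * a0(i) for i in range(t)),
                Fraction(0),
            )
            + _core0(n, qs, af)
        )

    if prof.which_case == "b1":  # t = 0, a = 1/2
        total = 2 * sum(
            (
                sum(
                    Fraction(comb(r, j - 1) * comb(j, k)) * bernoulli(j - k)
                    / (j * (2**j - 1))
                    for j in range(k, r + 1)
                )
                * ipow(nf, k)
                for k in range(1, r + 1)
            ),
            Fraction(0),
        )
        total -= 2
        lsum = sum(Fraction(comb(r, l), 2 ** (l + 1) - 1) for l in range(r))
        total += (1 - 2 * lsum) * (qs + nf * Fraction(2) ** (-qs) - 1)
        for i in range(r):
            coef = Fraction(comb(r, i), 2**i) + 2 * sum(
                Fraction(comb(r, l) * comb(l, i), 2 ** (l + 1) - 1)
                for l in range(i + 1, r)
            )
            total -= coef * a0(i)
        return total

    if prof.which_case == "b2":  # t = 0, a = 1
        total = sum(
            (
                sum(
                    Fraction(comb(r, j - 1) * comb(j, k)) * bernoulli(j - k)
                    / (j * (2 ** (j - 1) - 1))
                    for j in range(k, r + 1)
                )
                * ipow(nf, k)
                for k in range(2, r + 1)
            ),
            Fraction(0),
        )
        total += (
            qs + 1
            + sum(
                Fraction(comb(r, j)) * (bernoulli(j) - 1) / (2**j - 1)
                for j in range(1, r)
            )
        ) * nf
        total += 1 + sum(Fraction(comb(r, j), 2**j - 1) for j in range(1, r))
        total -= Fraction(2) ** (qs + 1)
        for i in range(r):
            coef = Fraction(comb(r, i), 2**i) + sum(
                Fraction(comb(r, l) * comb(l, i), 2**l - 1) for l in range(i + 1, r)
            )
            total -= coef * a0(i)
        return total

    if prof.which_case in ("b3", "b4"):  # t = 0, generic / a = 2^ell
        skip_i = t + ell + 1 if (prof.which_case == "b4") else None
        total = Fraction(0)
        for k in range(1, r + 1):
            coef = Fraction(0)
            for j in range(k, r + 1):
                if j == skip_i:
                    continue
                coef += Fraction(comb(r, j - 1) * comb(j, k)) * bernoulli(j - k) / (
                    j * (2 ** (j - 1) - af)
                )
            total += coef * ipow(nf, k)
        total += 1 / (af - 1)
        lsum = Fraction(0)
        for l in range(r):
            if prof.which_case == "b4" and l == ell:
                continue
            lsum += Fraction(comb(r, l)) / (2**l - af)
        core = (ipow(2 * af, qs) - 1) / (2 * af - 1) + nf * ipow(af, qs) - ipow(2 * af, qs)
        total += (1 - lsum) * core
        for i in range(r):
            coef = Fraction(comb(r, i), 2**i)
            for l in range(i + 1, r):
                if prof.which_case == "b4" and l == ell:
                    continue
                coef += Fraction(comb(r, l) * comb(l, i)) / (2**l - af)
            total -= coef * a0(i)
        if prof.which_case == "b4":
            bracket = T(1, qs, 2 * af) + qs * ipow(af, qs) * (nf - 2**qs)
            total += Fraction(comb(r, ell)) / af * bracket
            total += Fraction(comb(r, ell)) / af * sum(
                (comb(ell, i) * a1(i) for i in range(ell)), Fraction(0)
            )
        return total

    if prof.which_case == "c1":  # r, t >= 1, a = 1/2
        total = 2 * sum(
            (
                sum(
                    Fraction(binom(r, j - t - 1) * comb(j, k)) * bernoulli(j - k)
                    / (j * (2**j - 1))
                    for j in range(k, d + 1)
                )
                * ipow(nf, k)
                for k in range(1, d + 1)
            ),
            Fraction(0),
        )
        lsum = sum(Fraction(comb(r, l), 2 ** (t + l + 1) - 1) for l in range(r))
        total += (1 - 2 * lsum) * (qs + nf * Fraction(2) ** (-qs) - 1)
        for i in range(d):
            coef = (
                Fraction(binom(d, i), 2**i)
                - 2 * Fraction(binom(r, i - t), 2**i)
                - 2 * sum(
                    Fraction(comb(r, l) * binom(t + l, i), 2 ** (t + l + 1) - 1)
                    for l in range(max(0, i - t + 1), r)
                )
            )
            total += coef * a0(i)
        return total

    if prof.which_case == "c2":  # r, t >= 1, a = 1
        total = sum(
            (
                sum(
                    Fraction(binom(r, j - t - 1) * comb(j, k)) * bernoulli(j - k)
                    / (j * (2 ** (j - 1) - 1))
                    for j in range(k, d + 1)
                )
                * ipow(nf, k)
                for k in range(2, d + 1)
            ),
            Fraction(0),
        )
        total += (
            1
            + sum(
                Fraction(binom(r, j - t)) * (bernoulli(j) - 1) / (2**j - 1)
                for j in range(1, d)
            )
        ) * nf
        total += sum(Fraction(comb(r, l), 2 ** (t + l) - 1) for l in range(r)) - 1
        for i in range(d):
            coef = (
                Fraction(binom(d, i), 2**i)
                - 2 * Fraction(binom(r, i - t), 2**i)
                - sum(
                    Fraction(comb(r, l) * binom(t + l, i), 2 ** (t + l) - 1)
                    for l in range(max(0, i - t + 1), r)
                )
            )
            total += coef * a0(i)
        return total

    # c3 / c4: r, t >= 1, generic a or a = 2^(t+ell)
    is_c4 = prof.which_case == "c4"
    skip_j = t + ell + 1 if is_c4 else None
    total = Fraction(0)
    for k in range(1, d + 1):
        coef = Fraction(0)
        for j in range(k, d + 1):
            if j == skip_j:
                continue
            cb = binom(r, j - t - 1)
            if not cb:
                continue
            coef += Fraction(cb * comb(j, k)) * bernoulli(j - k) / (
                j * (2 ** (j - 1) - af)
            )
        total += coef * ipow(nf, k)
    if is_c4:
        bracket = T(1, qs, 2 * af) + qs * ipow(af, qs) * (nf - 2**qs)
        total += Fraction(comb(r, ell)) / af * bracket
    lsum = Fraction(0)
    for l in range(r):
        if is_c4 and l == ell:
            continue
        lsum += Fraction(comb(r, l)) / (2 ** (t + l) - af)
    core = (ipow(2 * af, qs) - 1) / (2 * af - 1) + nf * ipow(af, qs) - ipow(2 * af, qs)
    total += (1 - lsum) * core
    for i in range(d):
        coef = Fraction(binom(d, i), 2**i) - 2 * Fraction(binom(r, i - t), 2**i)
        for l in range(max(0, i - t + 1), r):
            if is_c4 and l == ell:
                continue
            coef -= Fraction(comb(r, l) * binom(t + l, i)) / (2 ** (t + l) - af)
        total += coef * a0(i)
    if is_c4:
        total += Fraction(comb(r, ell)) / af * sum(
            (comb(t + ell, i) * a1(i) for i in range(t + ell)), Fraction(0)
        )
    return total


def homogeneous(n: int, a, x1) -> Fraction:
    """Homogeneous solution term: the coefficient multiplying ``x_1``.

    ``x_n = ((2a)^q_s + (2a - 1)(n a^q_s - (2a)^q_s)) x_1``; returns x1 at n=1.
    """
    af, x1f = as_fraction(a), as_fraction(x1)
    if n < 1:
        raise ValueError("n must be >= 1")
    if x1f == 0:
        return Fraction(0)
    qs = decompose(n).top
    h = ipow(2 * af, qs) + (2 * af - 1) * (n * ipow(af, qs) - ipow(2 * af, qs))
    return h * x1f


def solve(spec: RecurrenceSpec, n: int) -> Fraction:
    """Closed-form value of the recurrence at n:
    ``sum b_{r,t} x_n^(r,t)(a) + homogeneous(n, a, x_1)``."""
    total = sum(
        (b * x_monomial(n, r, t, spec.a) for (r, t), b in spec.toll.coeffs.items()),
        Fraction(0),
    )
    return total + homogeneous(n, spec.a, spec.x1)


def oracle_solve(spec: RecurrenceSpec, n: int, _memo: dict | None = None) -> Fraction:
    """Ground truth: evaluate the recurrence by memoized top-down recursion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    memo = {1: spec.x1} if _memo is None else _memo
    return _oracle(spec, n, memo)


def _oracle(spec: RecurrenceSpec, n: int, memo: dict) -> Fraction:
    if n in memo:
        return memo[n]
    hi, lo = (n + 1) // 2, n // 2
    val = spec.a * (_oracle(spec, hi, memo) + _oracle(spec, lo, memo)) + spec.toll(hi, lo)
    memo[n] = val
    return val


def oracle_x_monomial(n: int, r: int, t: int, a) -> Fraction:
    """Memoized direct recursion for the monomial toll (x_1 = 0)."""
    return oracle_solve(
        RecurrenceSpec(a=as_fraction(a), toll=TollPolynomial({(r, t): 1})), n
    )


def toll_from_univariate(coeffs) -> TollPolynomial:
    """Expand a polynomial ``p(n) = sum c_k n^k`` (ascending coefficient list)
    into the bivariate toll table via ``n = ceil(n/2) + floor(n/2)``."""
    table: dict[tuple[int, int], Fraction] = {}
    for k, c in enumerate(coeffs):
        cf = as_fraction(c)
        if not cf:
            continue
        for j in range(k + 1):
            key = (j, k - j)
            table[key] = table.get(key, Fraction(0)) + cf * comb(k, j)
    return TollPolynomial(table)


def alternating_toll_expand(base: TollPolynomial, sign_coeff) -> TollPolynomial:
    """Rewrite a toll ``base(n) + c (-1)^n`` into the bivariate table using
    ``(-1)^n = 1 - 2(ceil(n/2) - floor(n/2))``."""
    c = as_fraction(sign_coeff)
    alt = TollPolynomial({(0, 0): c, (1, 0): -2 * c, (0, 1): 2 * c})
    return base + alt


def _univariate_shift(coeffs, delta: int) -> list[Fraction]:
    """Coefficients of ``p(y + delta)`` from those of ``p``."""
    out = [Fraction(0)] * max(len(coeffs), 1)
    for k, c in enumerate(coeffs):
        cf = as_fraction(c)
        for j in range(k + 1):
            out[j] += cf * comb(k, j) * ipow(Fraction(delta), k - j)
    return out


def stephan_transform(C, P=(), Q=(), x1=0) -> RecurrenceSpec:
    """Halving recurrence satisfied by ``x_n := a_{n-1}`` for an even/odd pair
    ``a_{2n} = C a_n + C a_{n-1} + P(n)``, ``a_{2n+1} = 2 C a_n + Q(n)``.

    The toll is ``Q(floor(n/2) - 1) + (ceil - floor)(P(floor) - Q(floor - 1))``,
    expanded into the bivariate table.  P and Q are ascending coefficient lists.
    """
    Cf = as_fraction(C)
    q_shift = _univariate_shift([as_fraction(c) for c in Q], -1)
    p_list = [as_fraction(c) for c in P]
    width = max(len(p_list), len(q_shift))
    diff = [
        (p_list[j] if j < len(p_list) else Fraction(0))
        - (q_shift[j] if j < len(q_shift) else Fraction(0))
        for j in range(width)
    ]
    table: dict[tuple[int, int], Fraction] = {}

    def _add(key, val):
        if val:
            table[key] = table.get(key, Fraction(0)) + val

    for j, c in enumerate(q_shift):
        _add((0, j), c)
    for j, dcoef in enumerate(diff):  # (x - y) * diff(y)
        _add((1, j), dcoef)
        _add((0, j + 1), -dcoef)
    return RecurrenceSpec(a=Cf, toll=TollPolynomial(table), x1=as_fraction(x1))


def vanishing_check(toll: TollPolynomial) -> bool:
    """True iff the toll yields the identically-zero solution with x_1 = 0.

    Tests the coefficient identities equivalent to ``P(x, x) = P(x, x-1) = 0``
    (i.e. ``P`` divisible by ``(x - y)(x - y - 1)``): for every total degree k,
    ``sum_j b_{j,k-j} = 0`` and ``sum_{l>=1} sum_j C(l+j, j) b_{l+j,k-j} = 0``.
    """
    d = toll.degree
    if d < 0:
        return True
    b = toll.coeffs
    for k in range(d + 1):
        s1 = sum((b.get((j, k - j), Fraction(0)) for j in range(k + 1)), Fraction(0))
        if s1 != 0:
            return False
        s2 = Fraction(0)
        for l in range(1, d - k + 1):
            for j in range(k + 1):
                s2 += comb(l + j, j) * b.get((l + j, k - j), Fraction(0))
        if s2 != 0:
            return False
    return True
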