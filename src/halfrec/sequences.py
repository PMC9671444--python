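"""Named integer/rational sequences with cross-validated evaluators.

Each sequence here solves a halving recurrence and is exposed through up to
three independent routes:

* ``closed`` — the explicit binary-decomposition formula,
* ``oracle`` — the memoized direct recursion on the defining recurrence,
* ``definitional`` — where one exists, a computation straight from the
  sequence's combinatorial definition (bitwise convolution loops, the
  signed-bit double sum, the Monroe--Job digit expression).

OEIS identifiers are labels only; values are validated internally, never
fetched.  The registry powers :func:`cross_validate` and the ``sequence`` CLI
command.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .binary import decompose
from .exact import Rational, ipow
from .solver import RecurrenceSpec, TollPolynomial, oracle_solve

__all__ = [
    "sackin_min",
    "colless_min",
    "cophenetic_min",
    "quartet_max",
    "walsh_lebesgue",
    "takagi_related",
    "monroe_job",
    "stanton_kocay",
    "stanton_kocay_definitional",
    "bitwise_sums",
    "bitwise_sums_definitional",
    "SequenceReport",
    "cross_validate",
    "sequence_names",
    "sequence_spec",
]


def sackin_min(n: int) -> Fraction:
    """Minimum Sackin index of a bifurcating tree with n leaves (A003314):
    ``S_n = (q_s + 2) n - 2^(q_s + 1)``."""
    qs = decompose(n).top
    return Fraction((qs + 2) * n - 2 ** (qs + 1))


def colless_min(n: int) -> Fraction:
    """Minimum Colless index with n leaves (A296062):
    ``c_n = sum_{i<s} 2^{q_i} (q_s - q_i - 2(s - i - 1))``."""
    bd = decompose(n)
    qs = bd.top
    return Fraction(
        sum(
            2 ** bd.q_at(i) * (qs - bd.q_at(i) - 2 * (bd.s - i - 1))
            for i in range(1, bd.s)
        )
    )


def cophenetic_min(n: int) -> Fraction:
    """Minimum total cophenetic index with n leaves (A174605):
    ``Phi_n = C(n,2) - s_n n - sum_i 2^(q_i - 1)(q_i - 2 i)``."""
    bd = decompose(n)
    acc = sum(
        Fraction(2) ** (bd.q_at(i) - 1) * (bd.q_at(i) - 2 * i)
        for i in range(1, bd.s + 1)
    )
    return comb(n, 2) - bd.s * n - acc


def quartet_max(n: int) -> Fraction:
    """Maximum rooted quartet index with n leaves (A300445), the simplified
    1/504 closed form in n and the ratios ``M_i(n) / 2^{q_i}``."""
    bd = decompose(n)
    nf = Fraction(n)
    s1 = Fraction(0)
    s2 = Fraction(0)
    for i in range(1, bd.s + 1):
        ratio = Fraction(bd.M_at(i), 2 ** bd.q_at(i))
        s1 += (1 + ratio) * (1 + 3 * ratio)
        s2 += bd.M_at(i) * (1 + ratio) ** 2
    return (
        9 * nf**4 - 42 * nf**3 + 63 * nf**2 - 6 * nf + 6 * nf * s1 - 18 * s2
    ) / 504


def walsh_lebesgue(n: int) -> Fraction:
    """Lebesgue constant of the n-th partial Walsh sum:
    ``lambda_n = s_n - sum_i 2^(-q_i) (n - M_i)``."""
    bd = decompose(n)
    return bd.s - sum(
        (
            Fraction(n - bd.M_at(i), 2 ** bd.q_at(i))
            for i in range(1, bd.s + 1)
        ),
        Fraction(0),
    )


def takagi_related(n: int, x1: Rational = Fraction(1)) -> Fraction:
    """Solution of ``x_n = x_ceil + x_floor + (-1)^n`` (Takagi-curve related):
    ``x_n = 2^(q_s + 2) + (x_1 - 3) n - 1 - 2 sum_{i<s} 2^{q_i}(q_s - q_i - 2(s - i))``.
    With x_1 = 1 this equals A268289 at odd index 2n - 1."""
    bd = decompose(n)
    qs = bd.top
    acc = sum(
        2 ** bd.q_at(i) * (qs - bd.q_at(i) - 2 * (bd.s - i)) for i in range(1, bd.s)
    )
    return Fraction(2) ** (qs + 2) + (Fraction(x1) - 3) * n - 1 - 2 * acc


def monroe_job(n: int) -> Fraction:
    """A268289 at index ``n - 1`` from the digit-by-digit expression
    ``sum_j [((floor(n/2^j) + 1) mod 2) 2^j + (-1)^((floor(n/2^j)+1) mod 2) (n mod 2^j)]``."""
    qs = decompose(n).top
    acc = 0
    for j in range(qs + 1):
        bit = (n >> j) + 1 & 1
        acc += bit * 2**j + (-1) ** bit * (n % 2**j)
    return Fraction(acc)


def stanton_kocay(n: int) -> Fraction:
    """Signed-bit partial sums (A005536 shifted): closed form
    ``(1/4) sum_i 2^{q_i} (1 - (-1)^{q_i} + 4 sum_{j>i} (-1)^{q_j})``."""
    bd = decompose(n)
    acc = Fraction(0)
    for i in range(1, bd.s + 1):
        tail = sum((-1) ** bd.q_at(j) for j in range(i + 1, bd.s + 1))
        acc += 2 ** bd.q_at(i) * (1 - (-1) ** bd.q_at(i) + 4 * tail)
    return acc / 4


def stanton_kocay_definitional(n: int) -> Fraction:
    """Definitional double sum ``x_n = sum_{k<n} sum_i (-1)^{q_i(k)}``."""
    acc = 0
    for k in range(1, n):
        acc += sum((-1) ** p for p in decompose(k).q)
    return Fraction(acc)


def _sigma1_closed(n: int) -> Fraction:
    """``sigma_{1,n}``: closed form of the AND-convolution recurrence at n."""
    bd = decompose(n)
    first = sum(
        (
            Fraction(bd.q_at(i)) * 2 ** bd.q_at(i)
            * (n - 2 ** bd.q_at(i) - 2 * bd.M_at(i + 1))
            for i in range(1, bd.s + 1)
        ),
        Fraction(0),
    )
    second = sum(
        ((n - bd.M_at(i)) * bd.M_at(i + 1) for i in range(1, bd.s + 1)),
        Fraction(0),
    )
    return first / 2 - second


def bitwise_sums(n: int) -> tuple[Fraction, Fraction, Fraction]:
    """Closed forms of ``(sum k AND (n-k), sum k XOR (n-k), sum k OR (n-k))``
    for k = 1..n-1 (A006581, A006582, A006583): the AND sum is the sigma_1
    closed form shifted to n + 1, the OR sum is ``2 C(n,2) - AND``, and XOR is
    their difference."""
    if n < 2:
        raise ValueError("bitwise sums need n >= 2")
    a1 = _sigma1_closed(n + 1)
    a3 = 2 * comb(n, 2) - a1
    return a1, a3 - a1, a3


def bitwise_sums_definitional(n: int) -> tuple[Fraction, Fraction, Fraction]:
    """Direct bitwise convolution loops."""
    a1 = sum(k & (n - k) for k in range(1, n))
    a2 = sum(k ^ (n - k) for k in range(1, n))
    a3 = sum(k | (n - k) for k in range(1, n))
    return Fraction(a1), Fraction(a2), Fraction(a3)


# ---------------------------------------------------------------------------
# registry

_TOLL_G1 = TollPolynomial({(1, 1): 1, (0, 2): -1})
_TOLL_G3 = TollPolynomial(
    {(0, 1): 4, (1, 0): 2, (0, 0): -6, (1, 1): -1, (0, 2): 1}
)


def _shifted(closed, offset: int):
    return lambda n: closed(n + offset)


@dataclass
class _Entry:
    spec: RecurrenceSpec
    closed: object
    definitional: object = None
    oracle_shift: int = 0  # sequence value at n is the recurrence at n + shift


_REGISTRY: dict[str, _Entry] = {
    "A003314": _Entry(
        RecurrenceSpec(a=1, toll=TollPolynomial({(1, 0): 1, (0, 1): 1})),
        sackin_min,
    ),
    "A296062": _Entry(
        RecurrenceSpec(a=1, toll=TollPolynomial({(1, 0): 1, (0, 1): -1})),
        colless_min,
    ),
    "A174605": _Entry(
        RecurrenceSpec(
            a=1,
            toll=TollPolynomial(
                {
                    (2, 0): Fraction(1, 2),
                    (1, 0): Fraction(-1, 2),
                    (0, 2): Fraction(1, 2),
                    (0, 1): Fraction(-1, 2),
                }
            ),
        ),
        cophenetic_min,
    ),
    "A300445": _Entry(
        RecurrenceSpec(
            a=1,
            toll=TollPolynomial(
                {
                    (2, 2): Fraction(1, 4),
                    (2, 1): Fraction(-1, 4),
                    (1, 2): Fraction(-1, 4),
                    (1, 1): Fraction(1, 4),
                }
            ),
        ),
        quartet_max,
    ),
    "walsh-lebesgue": _Entry(
        RecurrenceSpec(
            a=Fraction(1, 2),
            toll=TollPolynomial({(1, 0): Fraction(1, 2), (0, 1): Fraction(-1, 2)}),
            x1=1,
        ),
        walsh_lebesgue,
    ),
    "A268289": _Entry(
        RecurrenceSpec(
            a=1, toll=TollPolynomial({(0, 0): 1, (1, 0): -2, (0, 1): 2}), x1=1
        ),
        takagi_related,
        definitional=lambda n: monroe_job(2 * n),
    ),
    "A005536": _Entry(
        RecurrenceSpec(a=-1, toll=TollPolynomial({(0, 1): 1})),
        stanton_kocay,
        definitional=stanton_kocay_definitional,
    ),
    "A006581": _Entry(
        RecurrenceSpec(a=2, toll=_TOLL_G1),
        lambda n: bitwise_sums(n)[0],
        definitional=lambda n: bitwise_sums_definitional(n)[0],
        oracle_shift=1,
    ),
    "A006582": _Entry(
        RecurrenceSpec(a=2, toll=_TOLL_G3),  # a2 = a3 - a1, see cross_validate
        lambda n: bitwise_sums(n)[1],
        definitional=lambda n: bitwise_sums_definitional(n)[1],
        oracle_shift=1,
    ),
    "A006583": _Entry(
        RecurrenceSpec(a=2, toll=_TOLL_G3),
        lambda n: bitwise_sums(n)[2],
        definitional=lambda n: bitwise_sums_definitional(n)[2],
        oracle_shift=1,
    ),
}

# A006581/2/3 need n >= 2 (a sum over k = 1..n-1 of pairs)
_MIN_N = {"A006581": 2, "A006582": 2, "A006583": 2}


def sequence_names() -> list[str]:
    return sorted(_REGISTRY)


def sequence_spec(name: str) -> RecurrenceSpec:
    """The halving recurrence whose solution generates the named sequence."""
    try:
        return _REGISTRY[name].spec
    except KeyError:
        raise KeyError(f"unknown sequence {name!r}; known: {sequence_names()}") from None


@dataclass
class SequenceReport:
    """Per-n values of a named sequence from each available evaluator."""

    name: str
    n_range: tuple[int, int]
    closed: list[Fraction]
    oracle: list[Fraction]
    definitional: list[Fraction] | None
    agree: bool


def _oracle_column(name: str, lo: int, hi: int) -> list[Fraction]:
    entry = _REGISTRY[name]
    shift = entry.oracle_shift
    memo = {1: entry.spec.x1}
    if name == "A006582":  # XOR = OR - AND, both via their own recurrences
        memo1 = {1: Fraction(0)}
        spec1 = _REGISTRY["A006581"].spec
        return [
            oracle_solve(entry.spec, n + shift, memo)
            - oracle_solve(spec1, n + shift, memo1)
            for n in range(lo, hi + 1)
        ]
    return [oracle_solve(entry.spec, n + shift, memo) for n in range(lo, hi + 1)]


def cross_validate(name: str, n_max: int, n_min: int | None = None) -> SequenceReport:
    """Evaluate every route of a named sequence for n in [n_min, n_max] and
    compare the columns entrywise."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown sequence {name!r}; known: {sequence_names()}")
    entry = _REGISTRY[name]
    lo = n_min if n_min is not None else _MIN_N.get(name, 1)
    if n_max < lo:
        raise ValueError(f"n_max must be >= {lo} for {name}")
    closed = [entry.closed(n) for n in range(lo, n_max + 1)]
    oracle = _oracle_column(name, lo, n_max)
    definitional = (
        [entry.definitional(n) for n in range(lo, n_max + 1)]
        if entry.definitional
        else None
    )
    agree = closed == oracle and (definitional is None or definitional == closed)
    return SequenceReport(
        name=name,
        n_range=(lo, n_max),
        closed=closed,
        oracle=oracle,
        definitional=definitional,
        agree=agree,
    )
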