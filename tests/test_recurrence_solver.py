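"""Closed-form solver: case dispatch, monomial solutions, toll transforms."""

import random
from fractions import Fraction
from math import comb

import pytest

from conftest import A_GRID
from halfrec.solver import (
    RecurrenceSpec,
    TollPolynomial,
    alternating_toll_expand,
    case_profile,
    homogeneous,
    oracle_solve,
    oracle_x_monomial,
    solve,
    stephan_transform,
    toll_from_univariate,
    vanishing_check,
    x_monomial,
    x_monomial_cased,
)


class TestCaseProfile:
    @pytest.mark.parametrize(
        "r, t, a, ell, delta_ell, delta_rt, case",
        [
            (2, 0, 2, 1, 1, 1, "b4"),
            (1, 1, 3, None, 0, 0, "c3"),
            (1, 0, 1, 0, 1, 0, "b2"),
            (0, 3, "1/2", -4, 0, 0, "a"),
            (2, 0, "1/2", -1, 0, 1, "b1"),
            (3, 0, 7, None, 0, 1, "b3"),
            (2, 2, "1/2", -3, 0, 0, "c1"),
            (2, 2, 1, -2, 0, 0, "c2"),
            (2, 1, 4, 1, 1, 0, "c4"),
            (1, 0, 2, 1, 0, 1, "b3"),  # ell = 1 out of {0,...,r-1} = {0}
            (2, 0, -2, None, 0, 1, "b3"),  # negative a: ell undefined
        ],
    )
    def test_dispatch(self, r, t, a, ell, delta_ell, delta_rt, case):
        prof = case_profile(r, t, Fraction(a))
        assert prof.ell == ell
        assert prof.delta_ell == delta_ell
        assert prof.delta_rt == delta_rt
        assert prof.which_case == case

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            case_profile(1, 0, 0)


class TestMonomialSolutions:
    @pytest.mark.parametrize(
        "n, r, t, a, expected",
        [
            (5, 1, 0, 1, 7),
            (5, 0, 1, 1, 5),
            (8, 1, 0, 1, 12),
            (1, 2, 3, 5, 0),
        ],
    )
    def test_examples(self, n, r, t, a, expected):
        assert x_monomial(n, r, t, Fraction(a)) == expected
        assert oracle_x_monomial(n, r, t, Fraction(a)) == expected

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            x_monomial(0, 1, 0, Fraction(1))
        with pytest.raises(ValueError):
            x_monomial(5, 1, 0, 0)

    def test_matches_oracle_on_reduced_grid(self):
        for a in A_GRID:
            for r in range(4):
                for t in range(4):
                    spec = RecurrenceSpec(a=a, toll=TollPolynomial({(r, t): 1}))
                    memo = {1: Fraction(0)}
                    for n in range(1, 97):
                        assert x_monomial(n, r, t, a) == oracle_solve(
                            spec, n, memo
                        ), (n, r, t, a)

    def test_cased_formulas_match_general(self):
        """The nine algebraic specializations agree with the general formula
        everywhere on a grid covering every branch."""
        for a in A_GRID:
            for r in range(4):
                for t in range(4):
                    for n in range(1, 129):
                        assert x_monomial_cased(n, r, t, a) == x_monomial(
                            n, r, t, a
                        ), (n, r, t, a, case_profile(r, t, a).which_case)

    def test_every_case_label_is_exercised(self):
        labels = {
            case_profile(r, t, a).which_case
            for a in A_GRID
            for r in range(4)
            for t in range(4)
        }
        assert labels == {"a", "b1", "b2", "b3", "b4", "c1", "c2", "c3", "c4"}

    def test_power_of_two_indices(self):
        """At n = 2^m the solution collapses to a two-branch geometric form."""
        for a in A_GRID:
            for r in range(4):
                for t in range(4):
                    d = r + t
                    for m in range(1, 9):
                        if a == Fraction(2) ** (d - 1):
                            expected = Fraction(2) ** (d * (m - 1)) * m
                        else:
                            expected = (ipow2(2 * a, m) - Fraction(2) ** (m * d)) / (
                                2 * a - 2**d
                            )
                        assert x_monomial(2**m, r, t, a) == expected, (m, r, t, a)

    def test_symmetric_difference_identity(self):
        """Tolls (ceil - floor) and (ceil - floor)^m have the same solution."""
        for a in (Fraction(1), Fraction(2), Fraction(1, 2), Fraction(-1)):
            for m in range(1, 5):
                for n in (3, 7, 12, 33, 64, 100):
                    base = x_monomial(n, 1, 0, a) - x_monomial(n, 0, 1, a)
                    expanded = sum(
                        comb(m, p) * (-1) ** (m - p) * x_monomial(n, p, m - p, a)
                        for p in range(m + 1)
                    )
                    assert base == expanded, (a, m, n)


def ipow2(x, e):
    return Fraction(x) ** e if e else Fraction(1)


class TestHomogeneous:
    @pytest.mark.parametrize(
        "n, a, x1, expected", [(3, 2, 1, 10), (9, 5, 0, 0), (7, 1, 5, 35)]
    )
    def test_examples(self, n, a, x1, expected):
        assert homogeneous(n, Fraction(a), Fraction(x1)) == expected

    def test_matches_recursion(self):
        rng = random.Random(20240917)
        for a in A_GRID:
            x1 = Fraction(rng.randint(-9, 9), rng.randint(1, 7))
            spec = RecurrenceSpec(a=a, toll=TollPolynomial({}), x1=x1)
            memo = {1: x1}
            for n in range(1, 257):
                assert homogeneous(n, a, x1) == oracle_solve(spec, n, memo)


class TestSolve:
    def test_constant_toll_a_one(self):
        spec = RecurrenceSpec(a=1, toll=TollPolynomial({(0, 0): 1}))
        assert solve(spec, 9) == 8
        for n in range(1, 200):
            assert solve(spec, n) == n - 1  # (x1 + c) n - c with x1 = 0, c = 1

    def test_square_sequence(self):
        spec = RecurrenceSpec(
            a=2, toll=TollPolynomial({(0, 1): 1, (1, 0): -1}), x1=1
        )
        assert solve(spec, 11) == 121
        for n in range(1, 300):
            assert solve(spec, n) == n * n

    def test_walsh_lambda_small(self):
        spec = RecurrenceSpec(
            a=Fraction(1, 2),
            toll=TollPolynomial({(1, 0): Fraction(1, 2), (0, 1): Fraction(-1, 2)}),
            x1=1,
        )
        assert solve(spec, 3) == Fraction(3, 2)

    def test_random_specs_match_oracle(self):
        rng = random.Random(99173)
        for _ in range(20):
            a = rng.choice(A_GRID)
            toll = TollPolynomial(
                {
                    (rng.randint(0, 3), rng.randint(0, 3)): Fraction(
                        rng.randint(-5, 5), rng.randint(1, 4)
                    )
                    for _ in range(rng.randint(1, 3))
                }
            )
            x1 = Fraction(rng.randint(-6, 6), rng.randint(1, 5))
            spec = RecurrenceSpec(a=a, toll=toll, x1=x1)
            memo = {1: x1}
            for n in range(1, 129):
                assert solve(spec, n) == oracle_solve(spec, n, memo)

    def test_json_roundtrip(self):
        spec = RecurrenceSpec(
            a=Fraction(-1, 2),
            toll=TollPolynomial({(2, 1): Fraction(3, 7), (0, 0): -2}),
            x1=Fraction(5, 3),
        )
        again = RecurrenceSpec.from_json_dict(spec.to_json_dict())
        assert again.a == spec.a and again.x1 == spec.x1
        assert again.toll == spec.toll


class TestTollTransforms:
    def test_univariate_expansion(self):
        assert toll_from_univariate([0, 1]).coeffs == {(1, 0): 1, (0, 1): 1}
        assert toll_from_univariate([1]).coeffs == {(0, 0): 1}
        assert toll_from_univariate(
            [0, Fraction(-1, 2), Fraction(1, 2)]
        ).coeffs == {
            (2, 0): Fraction(1, 2),
            (1, 1): Fraction(1),
            (0, 2): Fraction(1, 2),
            (1, 0): Fraction(-1, 2),
            (0, 1): Fraction(-1, 2),
        }

    def test_univariate_expansion_solves_like_oracle(self):
        # p(n) = n^2 - 3n + 1 expanded to the bivariate table
        toll = toll_from_univariate([1, -3, 1])
        spec = RecurrenceSpec(a=Fraction(3, 2), toll=toll)
        memo = {1: Fraction(0)}

        def direct(n, memo={}):
            if n == 1:
                return Fraction(0)
            if n not in memo:
                hi, lo = (n + 1) // 2, n // 2
                memo[n] = Fraction(3, 2) * (direct(hi) + direct(lo)) + (
                    n * n - 3 * n + 1
                )
            return memo[n]

        for n in range(1, 100):
            assert solve(spec, n) == direct(n)

    def test_alternating_toll(self):
        alt = alternating_toll_expand(TollPolynomial({}), 1)
        assert alt.coeffs == {(0, 0): 1, (1, 0): -2, (0, 1): 2}
        assert alternating_toll_expand(TollPolynomial({}), 0).coeffs == {}
        scaled = alternating_toll_expand(TollPolynomial({}), 3)
        assert scaled.coeffs == {(0, 0): 3, (1, 0): -6, (0, 1): 6}
        # (-1)^n really is 1 - 2(ceil - floor)
        for n in range(2, 50):
            assert alt((n + 1) // 2, n // 2) == (-1) ** n

    def test_stephan_transform(self):
        homog = stephan_transform(1)
        assert homog.toll.coeffs == {} and homog.a == 1
        # pair a_{2n} = -a_n - a_{n-1} + n, a_{2n+1} = -2 a_n + (n + 1)
        # collapses to the half-recurrence with toll floor(n/2)
        spec = stephan_transform(-1, P=[0, 1], Q=[1, 1])
        assert spec.a == -1
        assert spec.toll.coeffs == {(0, 1): 1}
        # pair with C = 2 giving the AND-sum toll floor*(ceil - floor)
        spec = stephan_transform(2, P=[0, 1], Q=[])
        assert spec.toll.coeffs == {(1, 1): 1, (0, 2): -1}

    def test_stephan_transform_reproduces_pair(self):
        rng = random.Random(5)
        for _ in range(10):
            C = Fraction(rng.randint(-3, 3) or 1)
            P = [Fraction(rng.randint(-4, 4)) for _ in range(rng.randint(0, 3))]
            Q = [Fraction(rng.randint(-4, 4)) for _ in range(rng.randint(0, 3))]
            a0 = Fraction(rng.randint(-3, 3))
            # generate the sequence from the even/odd pair...
            seq = {0: a0}
            for n in range(1, 65):
                if n % 2 == 0:
                    k = n // 2
                    seq[n] = C * seq[k] + C * seq[k - 1] + _poly(P, k)
                else:
                    k = (n - 1) // 2
                    seq[n] = 2 * C * seq[k] + _poly(Q, k)
            # ...and check x_n := a_{n-1} satisfies the transformed recurrence
            spec = stephan_transform(C, P, Q, x1=a0)
            for n in range(2, 64):
                lhs = seq[n - 1]
                rhs = spec.a * (seq[(n + 1) // 2 - 1] + seq[n // 2 - 1]) + spec.toll(
                    (n + 1) // 2, n // 2
                )
                assert lhs == rhs, (C, P, Q, n)


def _poly(coeffs, x):
    return sum((c * Fraction(x) ** k for k, c in enumerate(coeffs)), Fraction(0))


def _poly_mul(p, q):
    out = {}
    for (r1, t1), b1 in p.items():
        for (r2, t2), b2 in q.items():
            key = (r1 + r2, t1 + t2)
            out[key] = out.get(key, Fraction(0)) + b1 * b2
    return out


class TestVanishingCriterion:
    FACTOR = {  # (x - y)(x - y - 1)
        (2, 0): Fraction(1),
        (1, 1): Fraction(-2),
        (0, 2): Fraction(1),
        (1, 0): Fraction(-1),
        (0, 1): Fraction(1),
    }

    def test_divisible_tolls_vanish(self):
        for q in [{(0, 0): Fraction(1)}, {(1, 1): Fraction(3), (0, 0): Fraction(2)}]:
            toll = TollPolynomial(_poly_mul(self.FACTOR, q))
            assert vanishing_check(toll)
            spec = RecurrenceSpec(a=Fraction(5, 3), toll=toll)
            memo = {1: Fraction(0)}
            for n in range(1, 201):
                assert solve(spec, n) == 0
                assert oracle_solve(spec, n, memo) == 0

    def test_non_divisible_tolls_do_not_vanish(self):
        for coeffs in [{(1, 0): 1, (0, 1): 1}, {(0, 0): 1}, {(2, 1): 1}]:
            toll = TollPolynomial(coeffs)
            assert not vanishing_check(toll)
            spec = RecurrenceSpec(a=Fraction(2), toll=toll)
            memo = {1: Fraction(0)}
            assert any(oracle_solve(spec, n, memo) != 0 for n in range(1, 17))

    def test_agrees_with_direct_substitution(self):
        rng = random.Random(31)
        for _ in range(40):
            toll = TollPolynomial(
                {
                    (rng.randint(0, 2), rng.randint(0, 2)): Fraction(
                        rng.randint(-3, 3)
                    )
                    for _ in range(rng.randint(1, 4))
                }
            )
            b = toll.coeffs
            on_diag = all(
                sum(
                    (b.get((r, k - r), Fraction(0)) for r in range(k + 1)),
                    Fraction(0),
                )
                == 0
                for k in range(toll.degree + 1)
            ) if toll.degree >= 0 else True
            # P vanishes for all n iff P(m, m) = P(m+1, m) = 0 for all m
            vanishes = all(
                toll(m, m) == 0 and toll(m + 1, m) == 0 for m in range(1, 12)
            )
            assert vanishing_check(toll) == vanishes, b
            if vanishes:
                assert on_diag
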