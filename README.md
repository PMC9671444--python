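# halfrec

Exact, finite closed-form solutions of **divide-and-conquer "halving"
recurrences**

```
x_n = a·x_⌈n/2⌉ + a·x_⌊n/2⌋ + P(⌈n/2⌉, ⌊n/2⌋),    n ≥ 2,
```

for any nonzero rational coefficient `a`, any bivariate polynomial toll
`P(x, y) = Σ b_{r,t} x^r y^t` with rational coefficients, and any initial
value `x_1` — together with the phylogenetics application that motivates
them: computing and normalizing **tree balance indices** (Sackin, Colless,
total cophenetic, rooted quartet) on rooted trees.

## Who is this for

Recurrences of this shape are ubiquitous: running times of balanced
divide-and-conquer algorithms (mergesort-type), scores of maximally balanced
phylogenetic trees, Lebesgue constants of the Walsh system, bitwise
convolution sums, and some two hundred OEIS "divide and conquer" sequences.
A Master Theorem only bounds their growth order. `halfrec` instead evaluates
`x_n` *exactly*, from a formula whose sums range over the set bits of `n` —
at most `⌊log2 n⌋ + 1` indices — and the degree of the toll, using exact
rational arithmetic throughout (no floats anywhere in the core).

For tree shape analysis this matters because normalizing a balance index
`I` to `[0, 1]` at each leaf count `n` requires its extreme values: the
caterpillar tree `K_n` is easy, but the maximally balanced tree `B_n`
satisfies exactly such a halving recurrence, e.g. for the total cophenetic
index `Φ(B_n) = Φ(B_⌈n/2⌉) + Φ(B_⌊n/2⌋) + C(⌈n/2⌉,2) + C(⌊n/2⌋,2)`.

## The method in one paragraph

Write `n = Σ_{j=1}^{s} 2^{q_j}` with `q_1 < … < q_s` and suffix sums
`M_i = Σ_{j≥i} 2^{q_j}`.  By linearity the solution splits into monomial
solutions `x_n^(r,t)(a)` (toll `⌈n/2⌉^r ⌊n/2⌋^t`, `x_1 = 0`) plus a
homogeneous term `((2a)^{q_s} + (2a−1)(n a^{q_s} − (2a)^{q_s}))·x_1`.  Each
monomial solution is a finite combination of Bernoulli-number coefficients,
geometric-type sums `T(d, n, x) = Σ_{k<n} k^d x^k`, and auxiliary sums

```
α_n^(d,m)(a) = Σ_{k<n} Σ_{j<s_k} q_j(k)^d (a 2^{−m})^{q_j(k)} M_{j+1}(k)^m
```

which themselves admit closed forms over the set bits of `n`.  When `a` is
an exact power of two `2^{t+ℓ}` with `ℓ ∈ {0,…,r−1}`, some denominators
`2^{t+l} − a` vanish; those indices are excluded and a compensating term in
the `α^(1,i)` sums appears.  This is why the implementation works over
`fractions.Fraction`: the case dispatch tests exact equalities that floating
point cannot decide.  Every closed form ships with an independent oracle
(memoized direct recursion, literal double sums, brute-force quartet
enumeration) and the test suite diffs them exactly.

## Worked example

Solve the minimum-Sackin recurrence `S_n = S_⌈n/2⌉ + S_⌊n/2⌋ + n`, `S_1 = 0`
(toll `n = ⌈n/2⌉ + ⌊n/2⌋`, i.e. coefficients `b_{1,0} = b_{0,1} = 1`):

```
$ halfrec solve --a 1 --toll 1,0:1 --toll 0,1:1 --x1 0 --from 5 --to 8 --check
n	x_n	oracle	agree
5	12	12	True
6	16	16	True
7	20	20	True
8	24	24	True
```

`x_n` is the closed-form value, `oracle` re-derives it by direct recursion;
`S_8 = 24` is the Sackin index of the balanced tree on 8 leaves (8 leaves at
depth 3).  The same number comes back from the tree layer:

```
$ printf '(((a,b),(c,d)),((e,f),(g,h)));\n' > balanced8.nwk
$ halfrec indices balanced8.nwk --normalize
tree_id	n	sackin	colless	cophenetic	quartet	sackin_norm	colless_norm	cophenetic_norm	quartet_norm
0	8	24	0	16	38	0	0	0	0
```

All four normalized indices are 0: this is the most balanced 8-leaf tree
(orientation: 0 = most balanced, 1 = caterpillar).  Named sequences are
cross-validated through up to three routes:

```
$ halfrec sequence A006581 --from 2 --to 5 --check
n	closed	oracle	definitional	agree
2	1	1	1	True
3	0	0	0	True
4	4	4	4	True
5	4	4	4	True
```

(`A006581(5) = Σ_{k=1}^{4} k AND (5−k) = 0+2+2+0 = 4`, computed from the
closed form of an `a = 2` halving recurrence, from the recursion, and from
the literal bitwise loop.)

Library use mirrors the CLI:

```python
>>> from fractions import Fraction
>>> from halfrec import RecurrenceSpec, TollPolynomial, solve, x_monomial
>>> spec = RecurrenceSpec(a=2, toll=TollPolynomial({(0, 1): 1, (1, 0): -1}), x1=1)
>>> solve(spec, 11)          # the recurrence satisfied by n^2
Fraction(121, 1)
>>> x_monomial(5, 1, 0, Fraction(1))
Fraction(7, 1)
```

## Layout

- `halfrec.binary` — binary decompositions `(s_n, q_i, M_i)`, halving
  composition lemma.
- `halfrec.exact` — Bernoulli numbers/polynomials, `T(d,n,x)`, Faulhaber
  sums, exact-rational plumbing.
- `halfrec.alphas` — the auxiliary sums `S`, `α`, `γ` and the consecutive
  difference formula, each with closed form and definitional oracle.
- `halfrec.solver` — case dispatch, the general monomial formula and its
  nine specializations, toll transforms, vanishing criterion, recursion
  oracle.
- `halfrec.sequences` — named cross-validated sequences (A003314, A296062,
  A174605, A300445, A005536, A268289, A006581–3, Walsh Lebesgue constants).
- `halfrec.trees` — Newick I/O, caterpillar / maximally balanced
  constructions, the four balance indices, extremes and normalization.
- `halfrec.cli` — the `halfrec` command.

See `docs/methods.md` for the mathematical conventions, design choices and
limitations.
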