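# Methods

## The problem

`halfrec` evaluates, exactly, the solution of the halving recurrence

    x_n = a·x_⌈n/2⌉ + a·x_⌊n/2⌋ + P(⌈n/2⌉, ⌊n/2⌋),   n ≥ 2,

given a nonzero rational `a`, a bivariate polynomial toll with rational
coefficients `b_{r,t}`, and an initial value `x_1`.  The class covers the
cost recurrences of balanced divide-and-conquer algorithms, the recurrences
satisfied by shape indices of maximally balanced phylogenetic trees, and
many OEIS "divide and conquer" sequences (including even/odd pairs
`a_{2n} = C a_n + C a_{n-1} + P(n)`, `a_{2n+1} = 2C a_n + Q(n)`, which the
`stephan_transform` helper rewrites into this form for `x_n := a_{n-1}`).

The asymptotic order of `x_n` follows a standard Master-Theorem trichotomy
in `a` versus `2^d` (`d` the toll degree); that classification is not what
this package computes.  The point is the *explicit value*, needed e.g. to
normalize balance indices where an asymptotic order is useless.

## Notation and conventions

For `n ≥ 1` write `n = Σ_{j=1}^{s_n} 2^{q_j(n)}` with
`0 ≤ q_1 < … < q_{s_n}` (so `q_{s_n} = ⌊log2 n⌋`) and define the suffix
sums `M_i(n) = Σ_{j≥i} 2^{q_j(n)} = 2^{q_i}⌊n/2^{q_i}⌋`.  Conventions used
everywhere, chosen so that boundary terms of telescoping sums come out
right:

- `q_0(n) = 0`, `M_0(n) = n + 1`, and `M_{s_n+1}(n) = 0`.  The out-of-range
  suffix sum must be 0 because the γ sums below index `M_{i+1}(k)` up to
  `i = s_k`.
- `0^0 = 1`, globally: in `T(d, n, x)` at `k = 0`, in `q_i^d` when
  `q_i = d = 0`, and in `M_{s+1}^0`.
- `q` and `M` are 1-indexed to match the standard notation; the accessors
  accept index 0 (and `s+1` for `M`) returning the conventions above.
- Arbitrary-precision integers and `fractions.Fraction` throughout; there
  is no floating point in the core, because the case dispatch below tests
  exact equalities like `a = 2^{t+ℓ}` and exact vanishing of denominators
  `2^{t+l} − a`.

Building blocks: Bernoulli numbers of the first kind (`B_1 = −1/2`),
generated by the defining recurrence `Σ_{k≤m} C(m+1,k) B_k = 0` into a
growable memoized table (never by a series); Bernoulli polynomials
`B_m(x)`; the double sequence `T(d,n,x) = Σ_{k<n} k^d x^k`, with the
standard closed forms for `d ∈ {0,1}` and direct summation for `d ≥ 2`
(only `d ≤ 1` occurs in the solver; larger `d` exists for oracle use); and
Faulhaber's Bernoulli expansion of `Σ_{k<n} k^d`.

## Structure of the solution

By linearity, `x_n = Σ_{r,t} b_{r,t}·x_n^(r,t)(a) + h_n(a)·x_1`, where
`x^(r,t)` solves the monomial-toll recurrence with zero initial value and
`h_n(a) = (2a)^{q_s} + (2a−1)(n a^{q_s} − (2a)^{q_s})` is the homogeneous
solution coefficient.

The monomial solution is assembled from the first differences
`y_n = x_n − x_{n−1}` (notably `y_2 = 1` independent of `r, t, a`), which
are expressed through the single-`n` sums

    S_n^(d,m) = Σ_{j=1}^{s_n−1} q_j(n)^d (a 2^{−m})^{q_j(n)} M_{j+1}(n)^m

and accumulate into

    α_n^(d,m)(a) = Σ_{k=1}^{n−1} S_k^(d,m).

The α's admit a finite closed form (a Bernoulli/T double sum over the set
bits of n, a middle sum over all but the highest bit, and a
`−T(d, q_s, 2a)` correction present only at `m = 0`); `halfrec.alphas`
implements both this closed form (`alpha_closed`, for `d ∈ {0,1}`, the only
degrees the solver needs) and the literal double sum (`alpha_bruteforce`,
any `d`) as independent code paths.  At `n = 1` all structures are empty
and both routes return 0 without special-casing.

A subtle and easy-to-get-wrong detail: the inner index of `S` runs to
`s_k − 1`, while the related γ sums

    γ_l(d,p,m) = Σ_{k=1}^{2^l−1} Σ_{i=1}^{s_k} q_i^d (a 2^{−m})^{q_i} M_{i+1}(k)^p

run to `s_k` — the difference is invisible except through the
`M_{s+1}^0 = 1` convention when `p = 0`.  Both upper limits are encoded
explicitly and cross-tested.  γ has three routes: the literal sum, the
`p = 0` reduction `2^{l−1} T(d, l, a2^{−m})`, and the Bernoulli-polynomial
closed form valid for `p < m` (with its `δ_{p=0, l>0}` correction term).

## Case dispatch

Let `ℓ = log2(a) − t` when `a` is an exact positive power of two, undefined
otherwise (detected exactly on rationals: numerator or denominator a power
of two and the other equal to 1; negative `a` never defines `ℓ`).  The
general formula excludes the summation indices `i = t+ℓ+1` and `l = ℓ`
whenever `ℓ` is a defined integer — precisely the indices whose
denominators `2^{i−1} − a`, `2^{t+l} − a` would vanish — and adds, when
additionally `r > 0` and `ℓ ∈ {0,…,r−1}` (`δ_ℓ = 1`), a compensating term

    (C(r,ℓ)/a)·(T(1,q_s,2a) + n q_s a^{q_s} − q_s (2a)^{q_s} + Σ_{i<t+ℓ} C(t+ℓ,i) α_n^(1,i)(a)).

Terms whose binomial coefficient `C(r, i−t−1)` is zero are skipped before
any division, so a vanishing denominator with zero numerator (which occurs
when `ℓ` is a negative integer) never produces a spurious 0/0.

`x_monomial` implements this single general formula.  `x_monomial_cased`
implements the nine algebraic specializations — `r = 0`; `t = 0` with
`a = 1/2`, `a = 1`, generic `a`, or `a = 2^ℓ` (`1 ≤ ℓ ≤ r−1`); and
`r, t ≥ 1` with the analogous four branches (`ℓ ∈ {0,…,r−1}` allowed in the
last) — and the suite asserts it equals `x_monomial` on a grid hitting
every branch.  `oracle_solve` (memoized top-down recursion, exact
arithmetic, O(log n) depth) is the ground truth both are compared against.
If any mismatch were found, the policy is: the recursion oracle is
authoritative and the offending `(n, r, t, a)` is reported, never patched
over.  (None has been found on the test grids.)

One transcription choice: the two power-of-two branches use the same
`T(1, q_s, 2a)`-based compensating bracket; an algebraically different
variant of that bracket that appears in one specialization was not
reproducible against the recursion oracle and was treated as a typo in the
source material.

## Vanishing tolls and toll transforms

The solution with `x_1 = 0` is identically zero iff `P(x,y)` is divisible
by `(x−y)(x−y−1)`, equivalently iff per total degree `k`:
`Σ_j b_{j,k−j} = 0` and `Σ_{l≥1} Σ_j C(l+j,j) b_{l+j,k−j} = 0`
(`vanishing_check` tests exactly these coefficient identities; the suite
confirms equivalence with direct substitution `P(m,m) = P(m+1,m) = 0`).

Univariate tolls `p(n)` are expanded through `n = ⌈n/2⌉ + ⌊n/2⌋`
(`toll_from_univariate`); tolls with a `(−1)^n` factor through
`(−1)^n = 1 − 2(⌈n/2⌉ − ⌊n/2⌋)` (`alternating_toll_expand`); even/odd pair
recurrences through the transformation described above
(`stephan_transform`).  These expansions are plain binomial identities
performed on exact coefficient tables.

## Named sequences

Each worked sequence registers up to three independent evaluators — closed
form, recursion oracle, and (where a natural one exists) a definitional
computation — and `cross_validate` diffs the columns exactly:

| label | recurrence | definitional route |
|---|---|---|
| A003314 | `a=1`, toll `n` | (tree layer: Sackin of `B_n`) |
| A296062 | `a=1`, toll `⌈n/2⌉−⌊n/2⌋` | (tree layer: Colless of `B_n`) |
| A174605 | `a=1`, toll `C(⌈n/2⌉,2)+C(⌊n/2⌋,2)` | (tree layer: cophenetic of `B_n`) |
| A300445 | `a=1`, toll `C(⌈n/2⌉,2)·C(⌊n/2⌋,2)` | (tree layer: quartet of `B_n`) |
| Walsh λ_n | `a=1/2`, toll `(⌈n/2⌉−⌊n/2⌋)/2`, `x_1=1` | — (the integral definition is out of scope) |
| A268289 (odd idx) | `a=1`, toll `(−1)^n`, `x_1=1` | Monroe–Job digit expression at `2n` |
| A005536 (shifted) | `a=−1`, toll `⌊n/2⌋` | double sum `Σ_{k<n} Σ_i (−1)^{q_i(k)}` |
| A006581/2/3 | `a=2`, tolls `g_1`, `g_3` (shift `n+1`) | literal bitwise AND/XOR/OR loops |

For the signed-bit sequence the inner exponent of the printed definition is
read as `(−1)^{q_i(k)}` (a `k`-independent exponent would make the inner
sum trivial); this reading agrees exactly with the recurrence oracle, which
settles the ambiguity.  OEIS identifiers are labels: nothing is fetched,
and the exact index alignment against OEIS numbering is not asserted —
internal three-way consistency is what is tested.

## Tree layer

`RootedTree` is a minimal labeled-tree structure; Newick parsing is
delegated to dendropy (branch lengths and internal labels parsed, then
ignored — all indices are topology-only), writing is native.  Duplicate
leaf labels are a validation error distinct from parse errors.

Indices: Sackin = sum of leaf depths; Colless = `Σ |κ_left − κ_right|`
(bifurcating only); total cophenetic = sum over leaf pairs of the depth of
their LCA, computed as `Σ_{v ≠ root} C(κ_v, 2)` with an explicit pairwise
evaluator as cross-check — the leaf-pair definition is the one consistent
with the `C(⌈n/2⌉,2)+C(⌊n/2⌋,2)` toll used by the recurrence (an
internal-node-pair variant sometimes stated does not reproduce that
recurrence); rooted quartet index = number of 4-leaf induced subtrees that
are two cherries, computed as `Σ_v C(κ_{v1},2)C(κ_{v2},2)` (each symmetric
quartet is rooted at exactly one 2–2 split) with a `C(n,4)` brute-force
evaluator for small `n`.  Multifurcating trees: Sackin and cophenetic are
computed (their definitions need no bifurcation); Colless and quartet raise
a domain error rather than silently generalizing.

Extremes and normalization: the balanced-side extreme of each index comes
from the closed formulas (minimum of Sackin/Colless/cophenetic, maximum of
quartet, attained on `B_n`); the caterpillar-side extreme is computed
directly on the constructed `K_n`, avoiding reliance on formulas the
package does not derive.  `normalize` maps to `[0,1]` with the repo
convention **0 = most balanced, 1 = caterpillar** (the quartet index, being
largest on balanced trees, is inverted); the orientation is a
documentation-level convention, not a mathematical necessity.  Degenerate
ranges (e.g. `n = 2`, or `n = 3` where the bifurcating topology is unique)
raise an explicit error naming `n`.

Trees are treated as unordered for all indices; Newick child order is
preserved only for round-trip output.

## Test design and problem sizes

Oracle-first: every closed form is compared against an independent
definitional route, exactly (`==` on `Fraction`), never within a tolerance.
The main grids: closed vs recursion for all `n ≤ 512`, `(r,t) ∈ {0..3}²`
and twelve coefficients `{1, −1, 2, −2, 4, 8, 1/2, −1/2, 3, 1/3, 3/2, 5}`
(chosen to hit all nine dispatch branches, verified by a test that the
label set is exactly the nine); α closed vs brute force for `n ≤ 512`,
`m ≤ 4`; γ for `l ≤ 8`; the `n²` self-identity to `n = 10⁴`; named
sequences to `n = 4096` (bitwise definitional loops, which cost O(n) per
term, to 256); tree-layer closure to `n = 256` (quartet to 64) plus
randomized cross-evaluator checks with fixed seeds.  These sizes keep the
full suite around a minute of CPU while covering every branch and every
carry/telescoping boundary (powers of two, `2^k − 1`, `2^k + 1` all occur
densely below the limits).

The package generates all of its own inputs; no fixture files exist.

## Known limitations

- Unequal coefficients on the ceiling and floor terms (including a zero
  one) are out of scope, as are non-polynomial tolls — e.g. factors
  `(−1)^{⌊n/2⌋}` — and irrational `a` (floats are converted verbatim to
  their exact binary rational, and `0.1 ≠ 1/10`; pass strings like
  `"1/10"`).
- `alpha_closed` is restricted to `d ∈ {0,1}` (all the solver needs); the
  brute-force route accepts any `d`.
- The closed form costs O(s_n · d²) rational operations per evaluation but
  exact rationals grow with `|a|^{log2 n}`; for huge `n` with large `|a|`
  the arithmetic, not the formula, is the bottleneck.
- `quartet_index_bruteforce` is O(n⁵)-ish and intended for `n ≲ 40`.
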