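from fractions import Fraction

import pytest

# coefficient grid that hits every branch of the closed solution: a = 1
# (tree indices), a = 1/2 (Walsh), negative a (signed-bit sums), powers of
# two 2, 4, 8 (bitwise sums / excluded-index branches), and non-dyadic
# rationals (generic branch)
A_GRID = tuple(
    Fraction(v)
    for v in (1, -1, 2, -2, 4, 8, "1/2", "-1/2", 3, "1/3", "3/2", 5)
)

A_GRID_SMALL = tuple(Fraction(v) for v in (1, -1, 2, "1/2", 3, "1/3", "3/2", 4, 8))


@pytest.fixture(scope="session")
def a_grid():
    return A_GRID


@pytest.fixture(scope="session")
def a_grid_small():
    return A_GRID_SMALL
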