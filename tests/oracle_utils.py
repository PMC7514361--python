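"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: exact rational
arithmetic for the descriptors, a literal O(N^2) evaluation of the DFT sum,
and a characteristic-polynomial eigen-solver for 3x3 matrices.
"""

import cmath
import itertools
from fractions import Fraction

import numpy as np


def brute_cid(perm):
    """Circular total variation / L, exactly, from the definition."""
    length = len(perm)
    tv = abs(perm[-1] - perm[0]) + sum(
        abs(a - b) for a, b in zip(perm, perm[1:])
    )
    return Fraction(tv, length)


def brute_cod(perm):
    """Mean displacement from the identity arrangement, exactly."""
    return Fraction(
        sum(abs(v - i) for i, v in enumerate(perm, start=1)), len(perm)
    )


def all_perms(n):
    return itertools.permutations(range(1, n + 1))


def naive_half_power(x):
    """Literal term-by-term DFT sum; squared moduli of the first half."""
    n2 = len(x)
    powers = []
    for k in range(n2 // 2):
        coeff = sum(
            x[i] * cmath.exp(-2j * cmath.pi * i * k / n2) for i in range(n2)
        )
        powers.append(abs(coeff) ** 2)
    return powers


def naive_full_energy(x):
    """Sum of |coeff|^2 over all 2N bins by literal evaluation."""
    n2 = len(x)
    total = 0.0
    for k in range(n2):
        coeff = sum(
            x[i] * cmath.exp(-2j * cmath.pi * i * k / n2) for i in range(n2)
        )
        total += abs(coeff) ** 2
    return total


def charpoly_eigen_3x3(m):
    """Eigenvalues of a symmetric 3x3 matrix via its characteristic polynomial."""
    m = np.asarray(m, dtype=float)
    assert m.shape == (3, 3)
    trace = m[0, 0] + m[1, 1] + m[2, 2]
    minors = (
        m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1]
        + m[0, 0] * m[2, 2] - m[0, 2] * m[2, 0]
        + m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    )
    det = np.linalg.det(m)
    roots = np.roots([1.0, -trace, minors, -det])
    return np.sort(roots.real)[::-1]
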