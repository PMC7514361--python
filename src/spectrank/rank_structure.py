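"""Rank vector, inverse permutation, and the rank-distance matrix.

Ranking the half-spectrum power values in descending order defines a
permutation of the grid indices: ``sigma[i]`` is the intensity rank of grid
point ``i`` (rank 1 = largest power) and the inverse permutation ``inv[r]``
is the grid location of the component holding rank ``r``.  The sequence
``inv`` — grid locations read off in rank order — is what the descriptors in
:mod:`spectrank.descriptors` operate on.

The rank-distance matrix ``M[r][s] = |inv[r] - inv[s]|`` collects the
absolute grid distances between every pair of ranked components.  It is
symmetric with zero diagonal, so its (real) eigenvalues sum to zero; the
eigenvalues and their partial sums summarize the matrix's structure.

Conventions
-----------
* Arrays are 0-indexed; rank and grid *values* are 1-based, matching the
  ``k = 1..N`` grid convention.
* Equal power values are ranked by lower grid index (stable tie-break); the
  number of tie groups is surfaced so callers can detect quantized or
  clipped inputs, where ranks are not trustworthy.
* Matrix rows/columns are indexed by rank.  The entry multiset (hence the
  eigenvalue spectrum) is the same under grid indexing, up to a symmetric
  permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .spectrum import PowerSpectrum

__all__ = ["RankVector", "DistanceMatrix", "rank_vector", "distance_matrix", "dismat_eigen"]


@dataclass
class RankVector:
    """Permutation pair linking grid locations and intensity ranks.

    Attributes
    ----------
    sigma
        ``sigma[i - 1]`` is the rank (1 = largest power) of grid point ``i``.
    inv
        ``inv[r - 1]`` is the grid point holding rank ``r``.
    ties_broken
        Number of groups of exactly equal power values that were resolved by
        the grid-index tie-break.
    """

    sigma: np.ndarray
    inv: np.ndarray
    ties_broken: int = 0

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=np.intp)
        inv = np.asarray(self.inv, dtype=np.intp)
        n = sigma.size
        if inv.size != n or n < 2:
            raise InvalidInputError("sigma and inv must have equal length >= 2")
        ident = np.arange(1, n + 1)
        if not (np.array_equal(np.sort(sigma), ident) and np.array_equal(np.sort(inv), ident)):
            raise InvalidInputError("sigma and inv must be permutations of 1..N")
        if not np.array_equal(sigma[inv - 1], ident):
            raise InvalidInputError("sigma and inv are not mutually inverse")
        self.sigma = sigma
        self.inv = inv

    @property
    def n(self) -> int:
        return self.sigma.size


@dataclass
class DistanceMatrix:
    """Symmetric integer matrix of absolute grid distances between ranks."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.entries)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        if not np.array_equal(m, m.T):
            raise InvalidInputError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise InvalidInputError("distance matrix must have zero diagonal")
        if np.any(m < 0):
            raise InvalidInputError("distance matrix entries must be nonnegative")
        self.entries = m.astype(np.intp)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


def rank_vector(ps: PowerSpectrum) -> RankVector:
    """Rank the spectrum's components in descending power order.

    Ties are broken deterministically by lower grid index; ``ties_broken``
    counts the tie groups encountered.
    """
    v = ps.values
    n = v.size
    if n < 2:
        raise InvalidInputError("ranking needs at least 2 grid points")
    # stable sort on negated values: equal powers keep ascending grid order
    order = np.argsort(-v, kind="stable")
    inv = order + 1
    sigma = np.empty(n, dtype=np.intp)
    sigma[order] = np.arange(1, n + 1)
    _, counts = np.unique(v, return_counts=True)
    ties = int(np.count_nonzero(counts > 1))
    return RankVector(sigma=sigma, inv=inv, ties_broken=ties)


def distance_matrix(rv: RankVector) -> DistanceMatrix:
    """Absolute grid-distance matrix between all pairs of ranked components."""
    inv = rv.inv
    entries = np.abs(inv[:, None] - inv[None, :])
    return DistanceMatrix(entries=entries)


def dismat_eigen(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the distance matrix and their partial sums.

    Returns
    -------
    eigenvalues
        Real eigenvalues sorted descending by signed value.
    partial_sums
        ``partial_sums[k]`` is the sum of the first ``k + 1`` eigenvalues;
        the last entry is the trace, i.e. zero up to round-off.
    """
    eigenvalues = np.linalg.eigvalsh(dm.entries.astype(np.float64))[::-1]
    return eigenvalues, np.cumsum(eigenvalues)
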