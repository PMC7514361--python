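"""Circular and correspondence difference descriptors of rank structure.

Both descriptors act on the inverse-permutation sequence ``inv`` — the grid
locations of the spectrum's components read in descending intensity order —
and map it to a scalar that *changes* when the spectrum's values are
permuted across the grid, unlike spectral entropy.

* CiD (circular difference) is the normalized circular total variation of
  ``inv``: the sum of absolute grid jumps between components of adjacent
  rank, closed into a cycle by the wrap-around term.  The wrap-around makes
  CiD invariant under cyclic rotation of the rank sequence.  Small CiD means
  similar intensities live at nearby frequencies.
* CoD (correspondence difference) is the normalized 1-norm distance of
  ``inv`` from the identity — the "perfectly ordered" spectrum whose k-th
  largest component sits at the k-th grid point.

Energy thresholding: on noisy wide-band signals the ranks of the many weak
components are unstable, so the descriptors can be restricted to the first
``L`` ranked components, where ``L`` is the smallest number of top
components whose powers sum to at least a fraction ``q`` of the total
energy.  The retained grid locations stay on the original grid ``1..N`` and
the normalization becomes ``1/L``.

For the full spectrum (``L = N``) exhaustive enumeration gives the exact
bounds ``2(N-1)/N <= CiD <= floor(N**2/2)/N`` (minimum at any monotone
arrangement) and ``0 <= CoD <= floor(N**2/2)/N`` (maximum at the reversal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, UndefinedEntropyError
from .rank_structure import RankVector, rank_vector
from .spectrum import PowerSpectrum, spectral_entropy

__all__ = [
    "DescriptorResult",
    "cid",
    "cod",
    "select_l",
    "describe",
    "cid_bounds",
    "cod_bounds",
]


@dataclass
class DescriptorResult:
    """Descriptors of one spectrum.

    ``cid``/``cod`` are computed on the first ``n_used = L`` ranked
    components; ``spectral_entropy`` (natural log) is always computed on the
    full spectrum.  ``cid`` is NaN when fewer than two components were
    retained.  ``ties_broken`` propagates the tie count from ranking.
    """

    cid: float
    cod: float
    spectral_entropy: float
    n_used: int
    q: float
    n_total: int
    ties_broken: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _as_distinct_prefix(inv_prefix: Sequence[int]) -> np.ndarray:
    arr = np.asarray(inv_prefix)
    if arr.ndim != 1:
        raise InvalidInputError("rank sequence must be one-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise InvalidInputError("rank sequence entries must be integers")
        arr = arr.astype(np.intp)
    if np.unique(arr).size != arr.size:
        raise InvalidInputError("rank sequence entries must be distinct")
    return arr.astype(np.float64)


def cid(inv_prefix: Sequence[int]) -> float:
    """Circular difference descriptor of a rank-ordered location sequence.

    ``(1/L) * (|inv[L] - inv[1]| + sum_i |inv[i] - inv[i+1]|)`` for a
    sequence of ``L >= 2`` distinct grid locations.
    """
    arr = _as_distinct_prefix(inv_prefix)
    length = arr.size
    if length < 2:
        raise InvalidInputError("cid needs at least 2 components")
    total_variation = abs(arr[-1] - arr[0]) + np.abs(np.diff(arr)).sum()
    return float(total_variation / length)


def cod(inv_prefix: Sequence[int]) -> float:
    """Correspondence difference descriptor.

    ``(1/L) * sum_i |inv[i] - i|``: mean grid displacement from the
    perfectly ordered arrangement, for ``L >= 1`` distinct locations.
    """
    arr = _as_distinct_prefix(inv_prefix)
    if arr.size < 1:
        raise InvalidInputError("cod needs at least 1 component")
    return float(np.abs(arr - np.arange(1, arr.size + 1)).sum() / arr.size)


def select_l(ps: PowerSpectrum, rv: RankVector, q: float) -> int:
    """Number of top-ranked components holding at least fraction ``q`` of energy.

    Returns the smallest ``L`` such that the ``L`` largest power values sum
    to ``>= q * total``.  ``q = 1`` selects every component that carries
    energy: exact-zero bins (e.g. a demeaned DC bin) are never retained,
    since they contribute nothing to any partial sum.
    """
    if not (0 < q <= 1):
        raise InvalidParameterError(f"q must be in (0, 1], got {q}")
    sorted_desc = ps.values[rv.inv - 1]
    cums = np.cumsum(sorted_desc)
    total = cums[-1]
    if not total > 0:
        raise InvalidInputError("cannot threshold an all-zero spectrum")
    # relative tolerance absorbs cumsum round-off without re-admitting
    # components of (numerically) zero energy
    return int(np.searchsorted(cums, q * total - 1e-12 * total, side="left")) + 1


# backwards-friendly alias matching the parameter's usual name in formulas
select_L = select_l


def describe(ps: PowerSpectrum, q: float = 1.0, demean_applied: bool = False) -> DescriptorResult:
    """Full descriptor set for one spectrum.

    Ranks the spectrum, selects the top ``L`` components by the energy
    threshold ``q``, and evaluates CiD and CoD on their grid locations.
    Spectral entropy is computed on the full spectrum regardless of ``q``.
    If only one component is retained, CiD is undefined and reported as NaN
    with a warning.
    """
    if not ps.values.sum() > 0:
        raise UndefinedEntropyError("descriptors undefined for all-zero spectrum")
    rv = rank_vector(ps)
    n_used = select_l(ps, rv, q)
    prefix = rv.inv[:n_used]
    if n_used >= 2:
        cid_value = cid(prefix)
    else:
        warnings.warn(
            "only one component retained by the energy threshold; CiD undefined",
            stacklevel=2,
        )
        cid_value = math.nan
    if rv.ties_broken:
        warnings.warn(
            f"{rv.ties_broken} tie group(s) in the power values; "
            "ranks were resolved by grid index",
            stacklevel=2,
        )
    return DescriptorResult(
        cid=cid_value,
        cod=cod(prefix),
        spectral_entropy=spectral_entropy(ps),
        n_used=n_used,
        q=q,
        n_total=ps.n,
        ties_broken=rv.ties_broken,
    )


def cid_bounds(n: int) -> tuple[float, float]:
    """Analytic (min, max) of CiD over all full-spectrum permutations of size n."""
    if n < 2:
        raise InvalidParameterError("bounds defined for n >= 2")
    return 2 * (n - 1) / n, (n * n // 2) / n


def cod_bounds(n: int) -> tuple[float, float]:
    """Analytic (min, max) of CoD over all full-spectrum permutations of size n."""
    if n < 2:
        raise InvalidParameterError("bounds defined for n >= 2")
    return 0.0, (n * n // 2) / n
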