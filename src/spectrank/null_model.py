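"""Null distributions of the descriptors under uniformly random permutations.

With no prior knowledge about a spectrum, every arrangement of the ranked
components is equally likely, so the natural null model for CiD and CoD is
the uniform distribution over all ``N!`` permutations.  For small grids
(``N <= 8``) the null is computed exactly by enumeration; for larger grids
by seeded Monte Carlo sampling of unbiased random permutations.

Closed forms (derivable from the uniform-pair identity
``E|X - Y| = (N + 1)/3`` for distinct uniform ``X, Y`` on ``1..N`` and from
``E sum |pi(i) - i| = (N**2 - 1)/3``):

* ``E[CiD_N] = (N + 1)/3``
* ``E[CoD_N] = (N**2 - 1)/(3N)``

Empirically the null distributions are close to Gaussian already at
moderate ``N`` even though their supports are bounded;
:func:`normal_fit_report` quantifies this with a moment-matched normal fit
and the quantile-quantile correlation.  :func:`z_score` standardizes an
observed descriptor value against a null.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

import numpy as np
from scipy import stats

from .errors import InvalidInputError, InvalidParameterError, UndefinedScoreError

__all__ = [
    "NullDistribution",
    "NormalFitReport",
    "exhaustive_null",
    "monte_carlo_null",
    "normal_fit_report",
    "z_score",
]

Descriptor = Literal["cid", "cod"]

EXHAUSTIVE_MAX_N = 8


def _descriptor_numerators(perms: np.ndarray, descriptor: Descriptor) -> np.ndarray:
    """Integer numerators (descriptor * n) for an array of permutations.

    ``perms`` has shape (reps, n) with 1-based entries.
    """
    if descriptor == "cid":
        wrap = np.abs(perms[:, -1] - perms[:, 0])
        return wrap + np.abs(np.diff(perms, axis=1)).sum(axis=1)
    if descriptor == "cod":
        ident = np.arange(1, perms.shape[1] + 1)
        return np.abs(perms - ident).sum(axis=1)
    raise InvalidParameterError(f"unknown descriptor {descriptor!r}")


@dataclass
class NullDistribution:
    """Null distribution of one descriptor at grid size ``n``.

    Exhaustive nulls store the exact value/probability table (and integer
    counts); Monte Carlo nulls store the raw samples.  ``mean_exact`` is the
    exact rational mean for exhaustive nulls.
    """

    n: int
    descriptor: Descriptor
    method: Literal["exhaustive", "monte_carlo"]
    mean: float
    std: float
    reps: int
    seed: int | None = None
    samples: np.ndarray | None = field(default=None, repr=False)
    values: np.ndarray | None = field(default=None, repr=False)
    counts: np.ndarray | None = field(default=None, repr=False)
    mean_exact: Fraction | None = field(default=None, repr=False)

    @property
    def probabilities(self) -> np.ndarray | None:
        if self.counts is None:
            return None
        return self.counts / self.counts.sum()

    def expanded_samples(self) -> np.ndarray:
        """All realizations as a flat array (repeating table values by count)."""
        if self.samples is not None:
            return self.samples
        assert self.values is not None and self.counts is not None
        return np.repeat(self.values, self.counts)

    def empirical_p_value(self, value: float, tail: Literal["lower", "upper"] = "lower") -> float:
        """Empirical tail probability of ``value`` under the null (with the
        add-one correction for Monte Carlo nulls)."""
        samples = self.expanded_samples()
        if tail == "lower":
            hits = int(np.count_nonzero(samples <= value))
        else:
            hits = int(np.count_nonzero(samples >= value))
        if self.method == "monte_carlo":
            return (hits + 1) / (samples.size + 1)
        return hits / samples.size

    def to_json(self, include_samples: bool = False) -> str:
        payload: dict = {
            "schema_version": 1,
            "n": self.n,
            "descriptor": self.descriptor,
            "method": self.method,
            "mean": self.mean,
            "std": self.std,
            "reps": self.reps,
            "seed": self.seed,
        }
        if self.values is not None and self.counts is not None:
            payload["values"] = self.values.tolist()
            payload["counts"] = self.counts.tolist()
        if include_samples and self.samples is not None:
            payload["samples"] = self.samples.tolist()
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NullDistribution":
        payload = json.loads(text)
        return cls(
            n=payload["n"],
            descriptor=payload["descriptor"],
            method=payload["method"],
            mean=payload["mean"],
            std=payload["std"],
            reps=payload["reps"],
            seed=payload.get("seed"),
            samples=np.asarray(payload["samples"]) if "samples" in payload else None,
            values=np.asarray(payload["values"]) if "values" in payload else None,
            counts=np.asarray(payload["counts"]) if "counts" in payload else None,
        )


def exhaustive_null(n: int, descriptor: Descriptor) -> NullDistribution:
    """Exact null over all ``n!`` permutations (``2 <= n <= 8``).

    The value table is exact: numerators are integers and each descriptor
    value is ``numerator / n``.  The mean is also provided as a
    :class:`fractions.Fraction`.
    """
    if not 2 <= n <= EXHAUSTIVE_MAX_N:
        raise InvalidParameterError(
            f"exhaustive enumeration supports 2 <= n <= {EXHAUSTIVE_MAX_N} "
            f"(got {n}); use monte_carlo_null for larger grids"
        )
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=np.intp)
    numerators = _descriptor_numerators(perms, descriptor)
    uniq, counts = np.unique(numerators, return_counts=True)
    total = int(math.factorial(n))
    mean_exact = Fraction(int((uniq * counts).sum()), n * total)
    second = Fraction(int((uniq * uniq * counts).sum()), n * n * total)
    var = second - mean_exact * mean_exact
    return NullDistribution(
        n=n,
        descriptor=descriptor,
        method="exhaustive",
        mean=float(mean_exact),
        std=math.sqrt(float(var)),
        reps=total,
        values=uniq / n,
        counts=counts,
        mean_exact=mean_exact,
    )


def monte_carlo_null(
    n: int, descriptor: Descriptor, reps: int = 64_000, seed: int = 0
) -> NullDistribution:
    """Monte Carlo null from ``reps`` seeded uniform random permutations."""
    if n < 2:
        raise InvalidParameterError("n must be >= 2")
    if reps < 100:
        raise InvalidParameterError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(1, n + 1), (reps, 1)), axis=1)
    samples = _descriptor_numerators(perms, descriptor) / n
    return NullDistribution(
        n=n,
        descriptor=descriptor,
        method="monte_carlo",
        mean=float(samples.mean()),
        std=float(samples.std(ddof=1)),
        reps=reps,
        seed=seed,
        samples=samples,
    )


@dataclass
class NormalFitReport:
    """Moment-matched normal fit and its quantile-quantile agreement."""

    mu: float
    sd: float
    qq_correlation: float


def normal_fit_report(nd: NullDistribution) -> NormalFitReport:
    """Fit a normal by moment matching and report the Q-Q correlation.

    The correlation is between the sorted realizations and the fitted
    normal's quantiles at the plotting positions ``(i - 0.5)/m``.  A value
    near 1 means the bounded-support null is well approximated by the
    Gaussian.  Degenerate (zero-variance) nulls report ``sd = 0`` and a NaN
    correlation.
    """
    samples = nd.expanded_samples()
    if nd.method == "monte_carlo" and samples.size < 100:
        raise InvalidInputError("normal fit needs at least 100 Monte Carlo samples")
    mu = float(samples.mean())
    sd = float(samples.std(ddof=1))
    if sd == 0:
        return NormalFitReport(mu=mu, sd=0.0, qq_correlation=math.nan)
    ordered = np.sort(samples)
    positions = (np.arange(1, samples.size + 1) - 0.5) / samples.size
    quantiles = stats.norm.ppf(positions, loc=mu, scale=sd)
    corr = float(np.corrcoef(ordered, quantiles)[0, 1])
    return NormalFitReport(mu=mu, sd=sd, qq_correlation=corr)


def z_score(value: float, nd: NullDistribution) -> float:
    """Standardized score of an observed descriptor value against a null."""
    if not nd.std > 0:
        raise UndefinedScoreError("z-score undefined for a degenerate null")
    return (value - nd.mean) / nd.std
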