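"""Half-spectrum power estimates and spectral entropy.

The analysis chain starts from an evenly sampled, real-valued signal of even
length ``2N``.  Applying the (unnormalized) discrete Fourier transform and
keeping the squared moduli of the first ``N`` coefficients yields the power
estimates ``Ps`` on the normalized angular-frequency grid, where the k-th
grid point (1-based) sits at ``(k - 1) * pi / N``.  Because the DFT of a real
signal is conjugate-symmetric, this half spectrum carries the full power
information apart from the Nyquist bin.

Spectral entropy is the Shannon entropy of ``Ps`` renormalized to a
probability vector.  It is invariant under any permutation of the spectrum —
precisely the invariance the rank-order descriptors in
:mod:`spectrank.descriptors` are designed to break.

Conventions
-----------
* The DFT is unnormalized: ``s_hat[k] = sum_i s[i] * exp(-2j*pi*i*k/(2N))``.
  Parseval's identity then reads ``sum_k |s_hat[k]|**2 = 2N * sum_i s[i]**2``
  over all ``2N`` bins; the half spectrum omits the conjugate half and the
  Nyquist bin.
* The DC bin is included by default.  Physiological recordings often carry a
  constant offset that pins rank 1 to DC, so ``demean=True`` subtracts the
  sample mean first (which zeroes the DC bin exactly).
* No taper/window is applied before the transform.
* Entropy uses the natural logarithm; ``normalized=True`` divides by
  ``ln N`` so values are comparable across grid sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedEntropyError

__all__ = ["Signal", "PowerSpectrum", "power_spectrum", "spectral_entropy"]

logger = logging.getLogger(__name__)


@dataclass
class Signal:
    """An evenly sampled real-valued signal.

    Parameters
    ----------
    samples
        Real sample values.  Odd-length input is truncated by one trailing
        sample (logged) so the length is an even ``2N``.
    rate
        Sampling rate in samples per second.  Optional: pure descriptor work
        on the normalized grid does not need it.
    """

    samples: np.ndarray
    rate: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise InvalidInputError(
                f"signal must be one-dimensional, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("signal contains non-finite samples")
        if samples.size % 2 == 1:
            logger.warning(
                "odd-length signal (%d samples): truncating one trailing sample",
                samples.size,
            )
            samples = samples[:-1]
        if self.rate is not None and not self.rate > 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.rate}")
        self.samples = samples

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n_grid(self) -> int:
        """Number of half-spectrum grid points, N = len // 2."""
        return self.samples.size // 2

    @property
    def duration(self) -> float | None:
        return None if self.rate is None else self.samples.size / self.rate


@dataclass
class PowerSpectrum:
    """Power estimates on the normalized half-spectrum grid ``[0, pi)``.

    ``values[k]`` (0-based) estimates the power at angular frequency
    ``k * pi / N``; in the 1-based grid convention used by the rank domain
    this is grid point ``k + 1``.
    """

    values: np.ndarray
    rate: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 1:
            raise InvalidInputError("power spectrum must be a nonempty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("power spectrum contains non-finite values")
        if np.any(values < 0):
            raise InvalidInputError("power spectrum contains negative values")
        self.values = values

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def grid(self) -> np.ndarray:
        """Normalized angular frequencies of the grid points."""
        return np.arange(self.n) * math.pi / self.n

    @property
    def frequencies(self) -> np.ndarray | None:
        """Grid in Hz if the originating sampling rate is known."""
        if self.rate is None:
            return None
        return np.arange(self.n) * self.rate / (2 * self.n)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def power_spectrum(signal: Signal, demean: bool = False) -> PowerSpectrum:
    """Half-spectrum power estimates of a signal.

    Parameters
    ----------
    signal
        Prepared signal of even length ``2N >= 4``.
    demean
        Subtract the sample mean before transforming; the DC bin is then
        exactly zero.

    Returns
    -------
    PowerSpectrum
        ``|s_hat[k]|**2`` for ``k = 0..N-1`` under the unnormalized DFT.
    """
    x = signal.samples
    if x.size < 4:
        raise InvalidInputError(
            f"signal must have at least 4 samples, got {x.size}"
        )
    if demean:
        x = x - x.mean()
    n = x.size // 2
    coeffs = np.fft.fft(x)[:n]
    values = np.abs(coeffs) ** 2
    if demean:
        values[0] = 0.0  # exact, not just within round-off
    return PowerSpectrum(values=values, rate=signal.rate)


def spectral_entropy(ps: PowerSpectrum, normalized: bool = False) -> float:
    """Shannon entropy of the power spectrum as a probability vector.

    Power values are divided by the total power to form probabilities
    ``p_i``; the entropy is ``-sum p_i ln p_i`` with ``0 ln 0 := 0``.  With
    ``normalized=True`` the result is divided by ``ln N`` and lies in
    ``[0, 1]``.

    Raises
    ------
    UndefinedEntropyError
        If the spectrum is identically zero.
    """
    total = ps.values.sum()
    if not total > 0:
        raise UndefinedEntropyError("spectral entropy undefined for all-zero spectrum")
    p = ps.values / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    if normalized:
        if ps.n < 2:
            raise InvalidInputError("normalized entropy needs at least 2 grid points")
        entropy /= math.log(ps.n)
    # clip tiny negative round-off on near-line spectra
    return max(entropy, 0.0)
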