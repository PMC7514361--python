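"""Synthetic signals and spectra with known rank structure.

Every other module is testable against these generators without external
data.  Two spectrum families share an arbitrary prescribed rank vector
while sitting at opposite ends of the entropy scale:

* the *flat* family — all components near ``1/N`` with a rank-realizing
  perturbation of size ``epsilon``; entropy tends to ``ln N`` as
  ``epsilon -> 0``;
* the *line* family — one dominant component carrying almost all energy,
  the rest of order ``epsilon``; entropy tends to 0.

Because both realize the same rank vector, they produce identical CiD/CoD:
an executable witness that the descriptors and spectral entropy measure
different things.

Time-domain generators produce multitone signals whose per-component power
ranks are set by amplitude (cosines at exact grid frequencies, so each
lands in a single bin), and long noise recordings with embedded bursts:
amplitude-modulated harmonic "syllables" (speech-like) or high-amplitude
low-frequency rhythmic "seizures" (EEG-like), with ground-truth boundaries
returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .spectrum import PowerSpectrum, Signal

__all__ = [
    "flat_spectrum",
    "line_spectrum",
    "multitone",
    "burst_signal",
    "Burst",
]

#: seizure-burst amplitude relative to the baseline noise SD
SEIZURE_AMPLITUDE_FACTOR = 3.0
#: syllable-burst amplitude relative to the baseline noise SD
SYLLABLE_AMPLITUDE_FACTOR = 6.0
#: seizure rhythm fundamental, Hz (ictal delta/theta range)
SEIZURE_FREQ_HZ = 3.0


def _check_target_inv(n: int, target_inv: Sequence[int]) -> np.ndarray:
    inv = np.asarray(target_inv, dtype=np.intp)
    if inv.size != n or not np.array_equal(np.sort(inv), np.arange(1, n + 1)):
        raise InvalidParameterError("target_inv must be a permutation of 1..n")
    return inv


def _epsilon_bound(n: int) -> float:
    # keeps both families positive, rank-safe, and (flat) near-uniform
    return 1.0 / (n * n)


def flat_spectrum(n: int, epsilon: float, target_inv: Sequence[int]) -> PowerSpectrum:
    """Near-flat spectrum realizing a prescribed rank vector.

    Grid point of rank ``r`` receives ``1/n + (n - r) * epsilon`` before
    normalization to unit total power, so ranks match ``target_inv``
    exactly for any admissible ``epsilon``.
    """
    inv = _check_target_inv(n, target_inv)
    if not 0 < epsilon < _epsilon_bound(n):
        raise InvalidParameterError(
            f"epsilon must lie in (0, {_epsilon_bound(n):g}) for n={n}"
        )
    values = np.empty(n)
    ranks = np.arange(1, n + 1)
    values[inv - 1] = 1.0 / n + (n - ranks) * epsilon
    return PowerSpectrum(values=values / values.sum())


def line_spectrum(n: int, epsilon: float, target_inv: Sequence[int]) -> PowerSpectrum:
    """Near-line spectrum realizing a prescribed rank vector.

    The rank-1 grid point carries ``1 - n(n-1)/2 * epsilon``; the grid point
    of rank ``r >= 2`` carries ``(n + 1 - r) * epsilon``.  Total power is
    exactly 1.
    """
    inv = _check_target_inv(n, target_inv)
    if not 0 < epsilon < _epsilon_bound(n):
        raise InvalidParameterError(
            f"epsilon must lie in (0, {_epsilon_bound(n):g}) for n={n}"
        )
    values = np.empty(n)
    ranks = np.arange(2, n + 1)
    values[inv[1:] - 1] = (n + 1 - ranks) * epsilon
    values[inv[0] - 1] = 1.0 - n * (n - 1) / 2 * epsilon
    if values[inv[0] - 1] <= (n - 1) * epsilon:
        raise InvalidParameterError("epsilon too large: dominant component not dominant")
    return PowerSpectrum(values=values)


def multitone(
    n_samples: int,
    rate: float,
    components: Sequence[tuple[int, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Signal:
    """Sum of cosines at exact grid frequencies plus seeded white noise.

    ``components`` lists ``(grid_index, amplitude)`` pairs with 1-based grid
    indices in ``1..n_samples/2``; grid index ``g`` maps to DFT bin
    ``g - 1``, so with ``noise_sd = 0`` each component occupies a single bin
    and the power ranks equal the amplitude ranks.  Note grid index 1 is the
    DC bin, whose power gets double weight relative to interior bins.
    """
    if n_samples < 4 or n_samples % 2:
        raise InvalidInputError("n_samples must be even and >= 4")
    half = n_samples // 2
    grid_indices = [g for g, _ in components]
    if len(set(grid_indices)) != len(grid_indices):
        raise InvalidParameterError("duplicate grid index in components")
    for g, _ in components:
        if not 1 <= g <= half:
            raise InvalidParameterError(f"grid index {g} outside 1..{half}")
    amplitudes = [a for _, a in components]
    if len(set(amplitudes)) != len(amplitudes):
        raise InvalidParameterError("component amplitudes must be distinct")
    i = np.arange(n_samples)
    x = np.zeros(n_samples)
    for g, a in components:
        x += a * np.cos(2 * np.pi * (g - 1) * i / n_samples)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n_samples)
    return Signal(samples=x, rate=rate)


@dataclass(frozen=True)
class Burst:
    """Ground-truth metadata of one embedded burst."""

    start_s: float
    end_s: float
    kind: str
    start_index: int
    end_index: int


def _syllable(t: np.ndarray, rate: float, amplitude: float) -> np.ndarray:
    """Amplitude-modulated harmonic stack, a crude voiced-syllable stand-in."""
    f0 = rate / 32  # keeps three harmonics well inside the band
    envelope = np.sin(np.pi * np.linspace(0, 1, t.size)) ** 2
    carrier = (
        1.0 * np.cos(2 * np.pi * f0 * t)
        + 0.6 * np.cos(2 * np.pi * 2 * f0 * t + 0.7)
        + 0.3 * np.cos(2 * np.pi * 3 * f0 * t + 1.3)
    )
    return amplitude * envelope * carrier


def _seizure(t: np.ndarray, amplitude: float) -> np.ndarray:
    """High-amplitude rhythmic activity with a weaker first harmonic."""
    return amplitude * (
        np.sin(2 * np.pi * SEIZURE_FREQ_HZ * t)
        + 0.4 * np.sin(2 * np.pi * 2 * SEIZURE_FREQ_HZ * t + 0.5)
    )


def burst_signal(
    total_s: float,
    rate: float,
    bursts: Sequence[tuple[float, float, str]],
    seed: int = 0,
    baseline_sd: float = 1.0,
) -> tuple[Signal, list[Burst]]:
    """Baseline white noise with non-overlapping bursts inserted.

    Parameters
    ----------
    total_s
        Total duration in seconds.
    rate
        Sampling rate, samples/s.
    bursts
        ``(start_s, end_s, kind)`` triples with ``kind`` in
        ``{"syllable", "seizure"}``; must lie within the duration and not
        overlap.
    seed
        Seed for the baseline noise generator.
    baseline_sd
        Baseline noise standard deviation; burst amplitudes scale with it
        (syllables 6x, seizures 3x).

    Returns
    -------
    (Signal, list[Burst])
        The signal and the ground-truth burst boundaries in both seconds
        and sample indices.
    """
    n = int(round(total_s * rate))
    if n < 4:
        raise InvalidInputError("signal too short")
    ordered = sorted(bursts, key=lambda b: b[0])
    for (s0, e0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            raise InvalidParameterError("bursts overlap")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, baseline_sd, n)
    meta: list[Burst] = []
    for start_s, end_s, kind in ordered:
        if not (0 <= start_s < end_s <= total_s):
            raise InvalidParameterError(
                f"burst ({start_s}, {end_s}) outside [0, {total_s}]"
            )
        i0, i1 = int(round(start_s * rate)), int(round(end_s * rate))
        t = np.arange(i0, i1) / rate
        if kind == "syllable":
            x[i0:i1] += _syllable(t, rate, SYLLABLE_AMPLITUDE_FACTOR * baseline_sd)
        elif kind == "seizure":
            x[i0:i1] += _seizure(t, SEIZURE_AMPLITUDE_FACTOR * baseline_sd)
        else:
            raise InvalidParameterError(f"unknown burst kind {kind!r}")
        meta.append(Burst(start_s, end_s, kind, i0, i1))
    return Signal(samples=x, rate=rate), meta
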