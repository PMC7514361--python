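"""Amplitude-integrated EEG (aEEG)-style envelope compression.

aEEG condenses hours of raw EEG into a bedside trend: the recording is
band-limited, rectified, enveloped, and every second is compressed to two
points — the upper and lower bound of the envelope within that second.  The
resulting 2-points-per-second trace is a suitable substrate for the
sliding-window descriptor monitoring in :mod:`spectrank.windowed`: seizures
appear as simultaneous jumps in the envelope's local energy and drops in
its rank irregularity.

The implementation keeps only the operational contract of that compression
(per-second upper/lower bounds of a band-limited rectified envelope); it is
not a reproduction of any published clinical aEEG pipeline — in particular
no asymmetric filtering or semilogarithmic display compression.  Filter
choices are exposed: zero-phase Butterworth band-pass over the conventional
aEEG band 2-15 Hz, rectification, and a 2 Hz zero-phase low-pass as the
envelope smoother.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InvalidInputError, InvalidParameterError
from .spectrum import Signal
from .windowed import WindowTrack, track

__all__ = ["AeegTrace", "to_aeeg", "monitor_aeeg"]


@dataclass
class AeegTrace:
    """Per-second upper/lower envelope bounds of a band-limited recording."""

    upper: np.ndarray
    lower: np.ndarray
    rate_in: float
    seconds: int

    def __post_init__(self) -> None:
        upper = np.asarray(self.upper, dtype=np.float64)
        lower = np.asarray(self.lower, dtype=np.float64)
        if upper.size != lower.size or upper.size != self.seconds:
            raise InvalidInputError("upper/lower must both have one point per second")
        if np.any(upper < lower):
            raise InvalidInputError("upper bound below lower bound")
        self.upper = upper
        self.lower = lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"upper": self.upper, "lower": self.lower})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def to_aeeg(
    signal: Signal,
    band: tuple[float, float] = (2.0, 15.0),
    envelope_hz: float = 2.0,
    order: int = 4,
) -> AeegTrace:
    """Compress a single-channel recording to a 2-points-per-second trace.

    Per second of input: band-pass filter, rectify, low-pass the rectified
    signal as the envelope, then take the envelope's max (upper) and min
    (lower) within that second.  A trailing partial second is dropped.

    Parameters
    ----------
    signal
        Single channel with a known sampling rate above ``2 * band[1]``.
    band
        Band-pass corner frequencies in Hz.
    envelope_hz
        Low-pass corner of the envelope smoother, Hz.
    order
        Butterworth order for both filters (applied zero-phase, so the
        effective order doubles).
    """
    if signal.rate is None:
        raise InvalidInputError("aEEG compression needs the sampling rate")
    rate = signal.rate
    per_second = int(round(rate))
    if abs(rate - per_second) > 1e-9:
        raise InvalidParameterError("aEEG compression needs an integer sampling rate")
    if rate <= 2 * band[1]:
        raise InvalidParameterError(
            f"sampling rate {rate} too low for band-pass up to {band[1]} Hz"
        )
    if not 0 < band[0] < band[1]:
        raise InvalidParameterError(f"invalid band {band}")
    x = signal.samples
    if x.size < per_second:
        raise InvalidInputError("need at least one full second of samples")
    sos_band = sps.butter(order, band, btype="bandpass", fs=rate, output="sos")
    sos_env = sps.butter(order, envelope_hz, btype="lowpass", fs=rate, output="sos")
    envelope = sps.sosfiltfilt(sos_env, np.abs(sps.sosfiltfilt(sos_band, x)))
    seconds = x.size // per_second
    blocks = envelope[: seconds * per_second].reshape(seconds, per_second)
    return AeegTrace(
        upper=blocks.max(axis=1),
        lower=blocks.min(axis=1),
        rate_in=rate,
        seconds=seconds,
    )


def monitor_aeeg(
    trace: AeegTrace,
    window: int = 128,
    step: int = 1,
    q: float = 0.9,
    bound: str = "upper",
) -> WindowTrack:
    """Descriptor monitoring of an aEEG trace.

    Runs :func:`spectrank.windowed.track` on the chosen bound sequence
    (default upper) at the trace's native 1 point/s rate.  LE is then the
    standard deviation of the last ``window`` trace points, and the
    monitoring value is ``log10(1 + LE)/log10(Descriptor)``.
    """
    if bound not in ("upper", "lower"):
        raise InvalidParameterError(f"bound must be 'upper' or 'lower', got {bound!r}")
    values = trace.upper if bound == "upper" else trace.lower
    if values.size < window:
        raise InvalidInputError(
            f"trace length {values.size} shorter than one window ({window})"
        )
    return track(Signal(samples=values, rate=1.0), window_length=window, step=step, q=q)
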