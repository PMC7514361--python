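"""Sliding-window descriptor tracks for long signals.

Change-point behaviour (speech syllable onsets, seizure onsets) shows up as
steep changes of the descriptors along a moving window.  For each window the
module computes the descriptor set, the local energy LE — the standard
deviation of the window's samples — and the monitoring value

    ``log10(1 + LE) / log10(Descriptor)``

which fuses irregularity (denominator) with energy (numerator): a burst of
energetic, rank-ordered activity drives the value up from both sides.  The
monitoring value is undefined when the descriptor is <= 1 (the denominator's
log is <= 0); such windows carry a NaN marker so plots and exports show
honest gaps rather than clamped values.

Windows are rectangular and right-aligned; reported times are window-END
sample indices, so the track is causal and each point uses only past data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import describe
from .errors import InvalidInputError, InvalidParameterError, UndefinedEntropyError
from .spectrum import PowerSpectrum, Signal

__all__ = ["WindowTrack", "track", "monitor_value"]

#: descriptor values closer to 1 than this have an unusable log denominator
_LOG_GUARD = 1e-9


@dataclass
class WindowTrack:
    """Per-window descriptor, energy, and monitoring tracks.

    All vectors share length ``floor((len(signal) - window_length)/step) + 1``.
    ``times`` holds 0-based indices of each window's last sample.  Undefined
    monitoring values (descriptor <= 1 or undefined CiD) are NaN.
    """

    window_length: int
    step: int
    q: float
    times: np.ndarray
    cid_track: np.ndarray
    cod_track: np.ndarray
    se_track: np.ndarray
    le_track: np.ndarray
    monitor_cid: np.ndarray
    monitor_cod: np.ndarray
    rate: float | None = None
    demean: bool = field(default=True, compare=False)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        end_time = (self.times + 1) / self.rate if self.rate else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "end_index": self.times,
                "end_time_s": end_time,
                "cid": self.cid_track,
                "cod": self.cod_track,
                "spectral_entropy": self.se_track,
                "le": self.le_track,
                "monitor_cid": self.monitor_cid,
                "monitor_cod": self.monitor_cod,
            }
        )

    def to_csv(self, path) -> None:
        # NaN markers export as empty cells
        self.to_frame().to_csv(path, index=False)


def monitor_value(descriptor_value: float, le: float) -> float:
    """Energy-weighted monitoring value ``log10(1 + LE)/log10(Descriptor)``.

    Returns NaN (with a warning) when the descriptor is not > 1, where the
    formula's denominator vanishes or flips sign.
    """
    if le < 0:
        raise InvalidInputError("local energy must be nonnegative")
    if not math.isfinite(descriptor_value) or descriptor_value <= 1 + _LOG_GUARD:
        warnings.warn(
            "monitoring value undefined for descriptor <= 1; emitting NaN",
            stacklevel=2,
        )
        return math.nan
    return math.log10(1 + le) / math.log10(descriptor_value)


def track(
    signal: Signal,
    window_length: int,
    step: int = 1,
    q: float = 1.0,
    demean: bool = True,
) -> WindowTrack:
    """Slide a window over the signal and compute descriptor tracks.

    Parameters
    ----------
    signal
        Input signal; must be at least one window long.
    window_length
        Window size in samples; even, >= 8.  The per-window grid size is
        ``N = window_length / 2``.
    step
        Hop between consecutive windows, in samples.
    q
        Energy-threshold fraction passed to the descriptors.
    demean
        Subtract each window's mean before the transform (default).  Offsets
        otherwise pin rank 1 to the DC bin in every window; monitoring
        targets the oscillatory structure.

    Notes
    -----
    LE is the population standard deviation of the window's raw (not
    demeaned) samples.  Windows whose spectrum is identically zero (constant
    window under ``demean``) yield NaN descriptors with a warning.
    """
    if window_length < 8 or window_length % 2:
        raise InvalidParameterError("window_length must be even and >= 8")
    if step < 1:
        raise InvalidParameterError("step must be >= 1")
    x = signal.samples
    if x.size < window_length:
        raise InvalidInputError(
            f"signal length {x.size} is shorter than one window ({window_length})"
        )
    starts = np.arange(0, x.size - window_length + 1, step)
    n_windows = starts.size
    half = window_length // 2
    cid_track = np.empty(n_windows)
    cod_track = np.empty(n_windows)
    se_track = np.empty(n_windows)
    le_track = np.empty(n_windows)
    mon_cid = np.empty(n_windows)
    mon_cod = np.empty(n_windows)
    for w, start in enumerate(starts):
        window = x[start : start + window_length]
        le = float(window.std())
        le_track[w] = le
        segment = window - window.mean() if demean else window
        values = np.abs(np.fft.fft(segment)[:half]) ** 2
        if demean:
            values[0] = 0.0
        try:
            result = describe(PowerSpectrum(values=values), q=q)
        except UndefinedEntropyError:
            warnings.warn(
                f"window ending at sample {start + window_length - 1} has zero "
                "spectrum; descriptors undefined",
                stacklevel=2,
            )
            cid_track[w] = cod_track[w] = se_track[w] = math.nan
            mon_cid[w] = mon_cod[w] = math.nan
            continue
        cid_track[w] = result.cid
        cod_track[w] = result.cod
        se_track[w] = result.spectral_entropy
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # NaN markers are expected in tracks
            mon_cid[w] = monitor_value(result.cid, le) if math.isfinite(result.cid) else math.nan
            mon_cod[w] = monitor_value(result.cod, le)
    return WindowTrack(
        window_length=window_length,
        step=step,
        q=q,
        times=starts + window_length - 1,
        cid_track=cid_track,
        cod_track=cod_track,
        se_track=se_track,
        le_track=le_track,
        monitor_cid=mon_cid,
        monitor_cod=mon_cod,
        rate=signal.rate,
        demean=demean,
    )
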