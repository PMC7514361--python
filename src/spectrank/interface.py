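"""File I/O and run configuration.

Supported input formats:

* WAV (PCM16 or float32) via :mod:`scipy.io.wavfile`; integer PCM is scaled
  to ``[-1, 1)``; stereo files use the first channel with a warning.
* CSV: one sample per row, ``.`` decimal, comma dialect; lines starting
  with ``#`` are comments, with the special form ``# rate=<Hz>`` supplying
  the sampling rate.
* EDF: single channel by label, read through :mod:`mne` (optional
  dependency).

Sample arrays are 0-indexed internally; the rank/grid domain downstream is
1-based (grid points ``k = 1..N``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InvalidInputError, InvalidParameterError
from .spectrum import Signal

__all__ = ["RunConfig", "read_signal", "write_signal_wav", "write_signal_csv"]

_FORMATS = ("wav", "csv", "edf")

_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # offset binary
}


@dataclass
class RunConfig:
    """Validated parameter bundle for a CLI run."""

    input_path: str
    fmt: str | None = None
    channel: str | None = None
    rate: float | None = None
    window_length: int = 1024
    step: int = 128
    q: float = 0.9
    demean: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise InvalidParameterError(f"q must be in (0, 1], got {self.q}")
        if self.window_length % 2 or self.window_length < 8:
            raise InvalidParameterError("window_length must be even and >= 8")
        if self.step < 1:
            raise InvalidParameterError("step must be >= 1")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise InvalidParameterError(
        f"cannot infer format from {path.name!r}; pass one of {_FORMATS}"
    )


def _read_wav(path: Path) -> Signal:
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        warnings.warn(
            f"{path.name}: multichannel WAV; using first channel", stacklevel=3
        )
        data = data[:, 0]
    scale = _PCM_SCALE.get(data.dtype)
    if scale is not None:
        offset = 128.0 if data.dtype == np.uint8 else 0.0
        data = (data.astype(np.float64) - offset) / scale
    return Signal(samples=np.asarray(data, dtype=np.float64), rate=float(rate))


def _read_csv(path: Path, rate: float | None) -> Signal:
    values: list[float] = []
    header_rate = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("rate="):
                    try:
                        header_rate = float(body.split("=", 1)[1])
                    except ValueError as exc:
                        raise InvalidInputError(
                            f"{path.name}:{lineno}: bad rate header {line!r}"
                        ) from exc
                continue
            try:
                values.append(float(line.split(",")[0]))
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path.name}:{lineno}: non-numeric sample {line!r}"
                ) from exc
    if not values:
        raise InvalidInputError(f"{path.name}: no samples found")
    return Signal(samples=np.asarray(values), rate=rate if rate is not None else header_rate)


def _read_edf(path: Path, channel: str | None) -> Signal:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise InvalidInputError(
            "EDF support requires the 'mne' package (install spectrank[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        raise InvalidInputError(
            f"EDF requires a channel label; available: {raw.ch_names}"
        )
    if channel not in raw.ch_names:
        raise InvalidInputError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0]
    return Signal(samples=data, rate=float(raw.info["sfreq"]))


def read_signal(
    path,
    fmt: str | None = None,
    channel: str | None = None,
    rate: float | None = None,
) -> Signal:
    """Read a single-channel signal from WAV, CSV, or EDF.

    Parameters
    ----------
    path
        Input file.
    fmt
        One of ``wav``/``csv``/``edf``; inferred from the extension when
        omitted.
    channel
        Channel label (EDF only).
    rate
        Sampling rate override (CSV files without a rate header).
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "wav":
        return _read_wav(path)
    if fmt == "csv":
        return _read_csv(path, rate)
    if fmt == "edf":
        return _read_edf(path, channel)
    raise InvalidParameterError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_signal_wav(path, signal: Signal) -> None:
    """Write a signal as float32 WAV (requires a known sampling rate)."""
    if signal.rate is None:
        raise InvalidInputError("WAV output needs a sampling rate")
    wavfile.write(path, int(round(signal.rate)), signal.samples.astype(np.float32))


def write_signal_csv(path, signal: Signal) -> None:
    """Write a signal as single-column CSV with a ``# rate=`` header."""
    with open(path, "w") as handle:
        if signal.rate is not None:
            handle.write(f"# rate={signal.rate:g}\n")
        for v in signal.samples:
            handle.write(f"{float(v)!r}\n")
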