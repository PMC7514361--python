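"""Exception hierarchy for spectrank.

All library errors derive from :class:`SpectrankError` so callers (and the
CLI) can separate data/parameter problems from programming errors.
"""


class SpectrankError(Exception):
    """Base class for all spectrank errors."""


class InvalidInputError(SpectrankError, ValueError):
    """A signal, spectrum or permutation violates an input contract."""


class InvalidParameterError(SpectrankError, ValueError):
    """A tunable parameter is outside its admissible range."""


class UndefinedEntropyError(SpectrankError, ArithmeticError):
    """Spectral entropy requested for an all-zero spectrum."""


class UndefinedScoreError(SpectrankError, ArithmeticError):
    """A calibrated score requested against a degenerate null distribution."""
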