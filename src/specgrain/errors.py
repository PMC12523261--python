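"""Exception hierarchy shared across the package."""


class SpecgrainError(Exception):
    """Base class for all package errors."""


class ConfigError(SpecgrainError):
    """Invalid configuration; the message names the offending field."""


class ParseError(SpecgrainError):
    """Malformed input file; the message carries a line/row number where known."""


class ShapeError(SpecgrainError):
    """Array dimensions incompatible with the operation."""


class FitError(SpecgrainError):
    """A model could not be fitted (degenerate data, divergence, ...)."""


class SelectionError(SpecgrainError):
    """A wavelength-selection procedure could not complete."""


class MetricError(SpecgrainError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""
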