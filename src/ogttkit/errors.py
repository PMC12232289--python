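"""Exception and warning types shared across the package."""


class OgttError(Exception):
    """Base class for all package errors."""


class SchemaError(OgttError):
    """A required column or schema entry is missing or malformed."""


class ParseError(OgttError):
    """A cell could not be parsed; carries the offending row index."""


class IntegrityError(OgttError):
    """Duplicate keys or cross-field inconsistencies in tabular input."""


class InputError(OgttError):
    """An operation's preconditions on its input data are not met."""


class DomainError(OgttError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class GridError(OgttError):
    """Time grids of two series/profiles do not match."""


class WindowError(OgttError):
    """An integration window contains too few sampled points."""


class DegenerateInputError(OgttError):
    """Input is degenerate (e.g. identically zero C-peptide)."""


class ParameterError(OgttError):
    """An unknown status / configuration key was requested."""


class ConfigError(OgttError):
    """A run or simulation configuration is invalid."""


class UnitSuspicionWarning(UserWarning):
    """Values are dimensionally suspect for the declared unit."""


class AnalysisWarning(UserWarning):
    """A statistical routine fell back or skipped part of its work."""
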