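"""Exception hierarchy.

Every error raised by the package derives from :class:`LangcalError`, so
callers (and the CLI) can map failure categories to exit codes without
string matching.
"""


class LangcalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LangcalError, ValueError):
    """Non-finite, out-of-domain or inconsistent numeric input."""


class InvalidParamsError(LangcalError, ValueError):
    """Isotherm parameters unusable for the requested operation
    (e.g. inversion with a <= 0 or b <= 0)."""


class SchemaError(LangcalError, ValueError):
    """A required column is missing from an input table."""


class ParseError(LangcalError, ValueError):
    """A table cell could not be parsed as the required type."""


class EmptyDatasetError(LangcalError, ValueError):
    """An operation received or produced a dataset with no usable rows."""


class UnderdeterminedFitError(LangcalError, ValueError):
    """Too few points or distinct concentrations to fit three parameters."""


class NoValidTrainingSetError(LangcalError, RuntimeError):
    """Every candidate training set was rejected by the Langmuir filter."""


class ConfigError(LangcalError, ValueError):
    """A simulation or CLI configuration violates its invariants."""
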