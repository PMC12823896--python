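"""Exception hierarchy shared across the screening pipeline.

Every error raised on a user-facing path derives from :class:`ScreeningError`,
and each subclass maps to a stable CLI exit code (see :mod:`lingscreen.cli`).
"""


class ScreeningError(Exception):
    """Base class for all lingscreen errors."""

    exit_code = 1


class ConfigError(ScreeningError):
    """Invalid configuration: bad split sizes, out-of-range k, unknown feature name."""

    exit_code = 2


class DataError(ScreeningError):
    """Malformed or unusable input data."""

    exit_code = 3


class FormatError(DataError):
    """A file does not follow its declared format (e.g. missing TSV column)."""


class EmptyTranscriptError(DataError):
    """No participant speech survived filtering; screening is undefined."""


class ParseError(DataError):
    """A CoNLL-U sentence violates the parsed-sentence invariants."""


class UndefinedFeatureError(DataError):
    """A feature has no value on this input (e.g. empty token list)."""


class InputError(DataError):
    """Non-finite or otherwise invalid numeric input."""


class ShapeError(DataError):
    """Array dimensions do not match the expected layout."""


class DegenerateLabelsError(ScreeningError):
    """A label vector with a single class where both classes are required."""

    exit_code = 4
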