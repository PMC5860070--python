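"""Exception hierarchy shared across the package."""


class AnnotrailError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AnnotrailError):
    """A record in an input file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(AnnotrailError):
    """Referential-integrity violation (e.g. entry cites an unknown release)."""


class ConfigError(AnnotrailError):
    """Invalid configuration (grouping map, synthesis parameters, ...)."""


class UnknownDatabaseError(AnnotrailError, LookupError):
    """A database identifier is not present in the index/corpus."""


class UnknownReleaseError(AnnotrailError, LookupError):
    """A release identifier is not present in a database's timeline."""


class BlankSentenceError(AnnotrailError, ValueError):
    """normalize() was handed an all-whitespace string."""


class UndefinedRatioError(AnnotrailError, ZeroDivisionError):
    """Percentage requested for a release with zero total sentences."""


class UnobservablePatternError(AnnotrailError):
    """Pattern detection requested on a corpus where it is unobservable
    (e.g. transience on a single-release database)."""
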