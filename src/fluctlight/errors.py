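"""Exception hierarchy for fluctlight.

All errors derive from :class:`FluctlightError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
malformed files, invalid data values, failed estimations and bad configs.
"""


class FluctlightError(Exception):
    """Base class for all fluctlight errors."""


class FormatError(FluctlightError):
    """A file could not be parsed into the expected table layout."""


class DataError(FluctlightError):
    """Parsed data violate an invariant (e.g. non-monotonic time)."""


class ValidationError(FluctlightError):
    """A table or trace fails a semantic requirement of an operation."""


class EstimationError(FluctlightError):
    """A fit or regression could not be carried out."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class ConfigError(FluctlightError):
    """A configuration file is invalid; lists the offending keys."""
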