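"""Exception hierarchy shared by all polyfp modules.

All validation failures derive from :class:`PolyfpError` so callers (and the
CLI) can distinguish bad input from programming errors.
"""


class PolyfpError(Exception):
    """Base class for all polyfp input/usage errors."""


class FormatError(PolyfpError):
    """A file does not conform to the expected tabular/FASTA dialect."""


class IntegrityError(PolyfpError):
    """A file parses but violates a cross-record consistency rule."""


class ValidationError(PolyfpError):
    """An in-memory argument violates an operation's precondition."""


class FitError(PolyfpError):
    """A mixture fit could not be performed (too few usable records, etc.)."""


class UsageError(PolyfpError):
    """Operation applied to objects it was not meant for (index mismatch,
    wrong marker/unit, empty selection)."""
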