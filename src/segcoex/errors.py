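"""Exception hierarchy.

All errors raised by segcoex derive from :class:`SegcoexError` so callers
(and the CLI) can distinguish input-contract violations from programming
errors.
"""


class SegcoexError(Exception):
    """Base class for all segcoex errors."""


class DataError(SegcoexError):
    """An input file or in-memory container violates its contract."""


class DesignError(SegcoexError):
    """A sample design is inconsistent with the expression matrix."""
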