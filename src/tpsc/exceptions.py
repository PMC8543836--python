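"""Exception hierarchy for the TPSC pipeline.

All anticipated failure modes derive from :class:`TPSCError` so callers
(and the CLI) can distinguish user/data problems from genuine bugs.
"""


class TPSCError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TPSCError):
    """Input violates a documented invariant (bad shape, duplicate ids, ...)."""


class ParseError(TPSCError):
    """A tabular input file could not be parsed."""


class EmptyResultError(TPSCError):
    """An operation removed every row/node (e.g. prefiltering left no genes)."""


class IsolatedNodeError(TPSCError):
    """A node has zero total potential energy and cannot be normalized."""


class NoCentersError(TPSCError):
    """The local-maximum search selected no centers; lower d_min or r."""
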