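"""Exception hierarchy shared across the toolkit.

``FormatError`` marks malformed input text (bad edge table, GMT line, ...);
``ContractError`` marks a violated numeric or structural precondition
(negative weight, f > min(G, s), non-symmetric matrix, ...).  The CLI maps
them to distinct exit codes.
"""


class DeathnetError(Exception):
    """Base class for all toolkit errors."""


class FormatError(DeathnetError):
    """An input file or stream does not conform to its text format."""


class ContractError(DeathnetError):
    """A documented precondition or invariant was violated."""
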