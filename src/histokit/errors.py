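"""Exception hierarchy shared across the toolkit.

Two error classes matter to callers: malformed or contradictory *input*
(:class:`InputError`) and input that is well-formed but carries no usable
signal (:class:`DegenerateDataError`, e.g. a flat k-mer histogram).  The CLI
maps them to exit codes 2 and 3 respectively.
"""


class HistokitError(Exception):
    """Base class for all toolkit errors."""


class InputError(HistokitError, ValueError):
    """Malformed, inconsistent or out-of-contract input."""


class DegenerateDataError(HistokitError, ValueError):
    """Structurally valid input from which no estimate can be formed."""
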