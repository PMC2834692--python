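"""Exception hierarchy.

All package-raised errors derive from :class:`IntronTraceError` so callers can
catch one type at the CLI boundary and map validation failures to a distinct
exit code.
"""


class IntronTraceError(Exception):
    """Base class for all errors raised by introntrace."""


class ValidationError(IntronTraceError):
    """Invalid input data (bad alphabet, schema violation, mismatched rows)."""


class ConfigError(IntronTraceError):
    """Invalid configuration values."""


class NoSplicedAlignmentError(IntronTraceError):
    """No block chain reaches the required protein coverage."""


class MalformedChainError(IntronTraceError):
    """Block chain is not colinear (overlapping or non-positive gaps)."""


class DegenerateScenarioError(IntronTraceError):
    """No informative leaf state for a gene; transfer inference impossible."""


class InternalConsistencyError(IntronTraceError):
    """Invariant violated inside the package (a bug, not a user error)."""
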