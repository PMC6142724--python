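"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (validation -> 2, format -> 3).
"""


class PrsRankError(Exception):
    """Base class for all package errors."""


class ValidationError(PrsRankError):
    """Input is well-formed but violates an invariant (e.g. duplicate ids)."""


class FormatError(PrsRankError):
    """Input file cannot be parsed as the expected format."""
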