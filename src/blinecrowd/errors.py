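"""Exception hierarchy for the crowd-labeling pipeline.

Errors are split by failure mode so callers (and the CLI) can distinguish
malformed files from internally inconsistent ones and from degenerate
statistical inputs.
"""


class BlinecrowdError(Exception):
    """Base class for all package errors."""


class FormatError(BlinecrowdError):
    """A file is missing required columns or required values."""


class ParseError(BlinecrowdError):
    """A cell value could not be parsed (reported with its row number)."""


class IntegrityError(BlinecrowdError):
    """A file violates an internal uniqueness/consistency constraint."""


class OrderingError(BlinecrowdError):
    """Events were supplied out of submission order."""


class CoverageError(BlinecrowdError):
    """A clip required by an operation is missing from an input map."""


class PairingError(BlinecrowdError):
    """An expert has no matching leave-one-out reference standard."""


class NormalizationError(BlinecrowdError):
    """Per-clip vote fractions do not sum to one."""


class DegenerateInputError(BlinecrowdError):
    """A statistic is undefined on this input (e.g. zero-variance differences)."""
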