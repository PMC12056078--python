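"""Exception hierarchy shared across the pipeline."""


class MegatxError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(MegatxError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidIntervalError(MegatxError, ValueError):
    """A genomic interval is malformed, out of bounds, or overlaps another."""


class DegenerateTrackError(MegatxError, ValueError):
    """A depth track cannot be normalized (e.g. all-zero coverage)."""


class InvalidInputError(MegatxError, ValueError):
    """A physiology record violates its invariants (e.g. zero biomass)."""


class MalformedReadError(MegatxError, ValueError):
    """A sequencing-read record could not be parsed; carries the record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class LayoutError(MegatxError, RuntimeError):
    """Circle layout resolution failed; carries the evidence table."""

    def __init__(self, message: str, evidence=None):
        super().__init__(message)
        self.evidence = evidence


class IncompleteCircleError(LayoutError):
    """Accepted adjacencies do not close into a single cycle."""


class AmbiguousLayoutError(LayoutError):
    """A competing adjacency has support too close to the accepted one."""
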