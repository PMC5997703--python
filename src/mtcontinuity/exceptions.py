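"""Exception hierarchy for mtcontinuity."""


class MtContinuityError(Exception):
    """Base class for all package errors."""


class AlignmentError(MtContinuityError):
    """Sequences are not a valid alignment (e.g. unequal lengths)."""


class FormatError(MtContinuityError):
    """Malformed or empty input file."""


class CoordinateError(MtContinuityError):
    """Requested coordinates fall outside the alignment or are empty."""


class MetadataError(MtContinuityError):
    """Sample metadata is missing or inconsistent."""


class PartitionError(MtContinuityError):
    """Group partition is invalid (overlap, undersized group, ...)."""


class NoInformativeSitesError(MtContinuityError):
    """All sites were filtered out; the statistic is undefined."""


class ModelError(MtContinuityError):
    """Demographic model or sampling schedule is invalid."""


class GridIncompleteError(MtContinuityError):
    """A verdict was requested from a grid that has not been fully evaluated."""
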