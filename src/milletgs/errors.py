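"""Exception hierarchy shared across the toolkit."""


class MilletGSError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MilletGSError, ValueError):
    """Invalid user-supplied parameter (out-of-range frequency, bad counts)."""


class DataError(MilletGSError, ValueError):
    """Input data violates a contract (missing QTL genotype, bad dosage)."""


class LayoutError(MilletGSError, ValueError):
    """Field-design layout cannot be constructed from the given entries."""


class ModelError(MilletGSError, ValueError):
    """Mixed-model fit is degenerate or failed to converge."""


class AlignmentError(MilletGSError, KeyError):
    """Marker or entry identifiers do not line up between two objects."""


class CoordinateError(MilletGSError, ValueError):
    """Two marker sets use incompatible genome coordinate naming."""
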