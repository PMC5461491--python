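"""Exception hierarchy shared across the package."""


class AntsignsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AntsignsError):
    """A file could not be parsed into the expected tabular/structured form."""


class GeometryError(AntsignsError):
    """A nest geometry violates its invariants (overlap, degenerate polygon...)."""


class ParameterError(AntsignsError, ValueError):
    """An argument is outside its documented domain."""


class SampleSizeError(AntsignsError):
    """Too few observations for the requested statistic."""


class NormalizationError(AntsignsError):
    """A per-experiment feature normalization has a zero divisor."""


class TrainingError(AntsignsError):
    """A classifier cannot be fitted from the given samples."""


class LeakageError(AntsignsError):
    """Train and test sets share experiment identifiers."""


class BinningError(AntsignsError):
    """Requested binning leaves a bin with too few records."""


class SizeError(AntsignsError):
    """Problem size exceeds what the exact algorithm enumerates."""
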