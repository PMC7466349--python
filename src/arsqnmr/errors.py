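"""Named exceptions raised across the pipeline.

Every contract violation surfaces as one of these rather than a bare
ValueError, so callers (and the CLI) can distinguish bad physics from bad
files from bad statistics.
"""


class ArsQnmrError(Exception):
    """Base class for all package errors."""


class ValidationError(ArsQnmrError, ValueError):
    """A domain object or argument violates its invariants."""


class EfficiencyError(ValidationError):
    """Extraction efficiency outside (0, 1]."""


class SweepWindowError(ValidationError):
    """A resonance falls outside the acquired sweep window (would alias)."""


class EmptyFIDError(ValidationError):
    """FID contains no points."""


class PhaseError(ArsQnmrError):
    """Automatic phasing failed to converge (result still returned, flagged)."""


class WindowOverlapError(ValidationError):
    """Two ppm windows that must be disjoint overlap."""


class PeakNotFoundError(ArsQnmrError):
    """No peak above the detection threshold in the search window."""


class InternalStandardError(ArsQnmrError):
    """Internal-standard integral is missing, non-positive or below noise."""


class BelowDetectionError(ArsQnmrError):
    """A validation study was requested on a sample below LOD/LOQ."""


class JcampParseError(ArsQnmrError):
    """Malformed JCAMP-DX input; message carries line context."""


class UnsupportedDimensionError(JcampParseError):
    """JCAMP-DX file holds multi-dimensional data (only 1D supported)."""


class UnknownPresetError(ValidationError):
    """Requested sample preset does not exist; message lists available ones."""
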