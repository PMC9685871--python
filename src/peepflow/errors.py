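"""Exception hierarchy for peepflow.

Every error raised by the library derives from :class:`PeepflowError`, so
callers can catch one type at pipeline level and log the breath or
acquisition that failed.
"""


class PeepflowError(Exception):
    """Base class for all peepflow errors."""


class SchemaError(PeepflowError):
    """A declared waveform column is missing or a schema entry is invalid."""


class SamplingError(PeepflowError):
    """The time base is not uniformly sampled within tolerance."""


class FormatError(PeepflowError):
    """A file does not have the expected on-disk layout (e.g. EIT grid shape)."""


class AlignmentError(PeepflowError):
    """Waveform and EIT timelines do not overlap after applying the offset."""


class PartitionError(PeepflowError):
    """An ROI band is empty after masking, or bands are malformed."""


class CoverageError(PeepflowError):
    """EIT frames do not cover the requested breath window."""


class DegenerateBreathError(PeepflowError):
    """Total tidal impedance change is non-positive; the breath is unusable."""


class ConditioningError(PeepflowError):
    """The regression design matrix is rank deficient or ill conditioned."""


class RoutingError(PeepflowError):
    """Samples are too small or degenerate for normality routing."""


class UndefinedTestError(PeepflowError):
    """All paired differences are zero; the signed-rank test is undefined."""


class DegenerateDesignError(PeepflowError):
    """All predictor values identical; a regression line is undefined."""


class SimulationError(PeepflowError):
    """The breath-dynamics integration produced a non-finite state."""


class ManifestError(PeepflowError):
    """A data directory contains unmatched waveform/EIT pairs."""
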