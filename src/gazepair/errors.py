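"""Exception types raised across the package."""


class GazepairError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GazepairError):
    """Invalid grid / strategy / pipeline configuration."""


class InvalidSampleError(GazepairError):
    """A gaze sample with non-finite coordinates was passed to geometry code."""


class SchemaError(GazepairError):
    """A data file does not match the expected column schema."""


class IntegrityError(GazepairError):
    """A data file parses but violates an ordering or consistency constraint."""


class UndefinedMetricError(GazepairError):
    """A metric was requested on input for which it is not defined
    (e.g. precision of a single sample, entropy of an all-zero count vector)."""


class InvalidMatrixError(GazepairError):
    """A transition-count matrix violates its structural constraints
    (e.g. non-zero diagonal)."""
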