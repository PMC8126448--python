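"""Error types shared across the pipeline stages."""


class MetabodnmError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetabodnmError):
    """Invalid configuration (non-PSD covariance, sizes that do not partition, ...)."""


class DesignError(MetabodnmError):
    """The paired two-condition study design is violated (unpaired subject, too few samples, single condition)."""


class FormatError(MetabodnmError):
    """Malformed input table (duplicate metabolite IDs, missing columns)."""


class AlignmentError(MetabodnmError):
    """Two results refer to different metabolite sets."""


class DegenerateDataError(MetabodnmError):
    """Data carry no usable variation (e.g. all sample variances zero)."""


class NumericalError(MetabodnmError):
    """An iterative numerical routine failed to converge."""
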