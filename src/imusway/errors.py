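"""Exception hierarchy for the imusway pipeline."""


class ImuswayError(Exception):
    """Base class for all imusway errors."""


class ConfigurationError(ImuswayError):
    """Invalid configuration value; message names the offending field."""


class ParseError(ImuswayError):
    """Malformed recording or table file; message carries the row number."""


class ModelError(ImuswayError):
    """Invalid simulation-model parameters (non-finite, unstable, ...)."""


class ExtractionError(ImuswayError):
    """Feature extraction failed; message lists the failing measure."""


class SpectralError(ImuswayError):
    """Series too short (or otherwise unfit) for spectral estimation."""


class IntegrityError(ImuswayError):
    """Inconsistent dataset, e.g. one subject ID spanning both groups."""


class SchemaError(ImuswayError):
    """Feature schemas disagree; message names the divergent feature."""


class EvaluationError(ImuswayError):
    """Classification evaluation cannot proceed (single-class fold, ...)."""


class CapacityError(ImuswayError):
    """Requested exact method exceeds its tractable problem size."""
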