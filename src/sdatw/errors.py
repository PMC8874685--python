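"""Exception hierarchy for the sdatw package."""


class SdatwError(Exception):
    """Base class for all package errors."""


class FormatError(SdatwError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(SdatwError):
    """Data violates a structural invariant (ordering, overlap, monotonicity)."""


class ValidationError(SdatwError):
    """A value is outside its allowed vocabulary or range."""


class DetectionError(SdatwError):
    """A required signal feature (stomp, event) could not be found."""


class SynchronizationError(SdatwError):
    """Sensor and label streams cannot be aligned."""


class DegenerateInputError(SdatwError):
    """Input is degenerate for the requested operation (e.g. constant series)."""


class ParameterError(SdatwError):
    """An operation parameter is invalid."""
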