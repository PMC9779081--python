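"""Exception hierarchy shared across the package."""


class ImmunoPKError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedParameterizationError(ImmunoPKError):
    """Raised for parameter sets the model does not define (e.g. repeated eigenvalues)."""


class InconsistentEigenstructureError(ImmunoPKError):
    """Raised when (lambda_b, lambda_p, K_pb) cannot come from a valid rate matrix."""


class InsufficientDataError(ImmunoPKError):
    """Raised when a fit is requested with too few or non-finite data points."""


class IllPosedParametersError(ImmunoPKError):
    """Raised when kinetic parameters make the model ill-posed (e.g. K_in + K_out = 0)."""


class InvalidStateError(ImmunoPKError):
    """Raised when a state vector contains negative or non-finite amounts."""


class MissingParameterError(ImmunoPKError):
    """Raised when a required rate-table entry is absent."""


class CorruptedFixtureError(ImmunoPKError):
    """Raised when a bundled data file fails its checksum."""


class SchemaError(ImmunoPKError):
    """Raised when a file does not conform to the expected tabular schema."""
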