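"""Exception hierarchy shared across the pipeline stages."""


class GCTetraError(Exception):
    """Base class for all package errors."""


class InvalidModelError(GCTetraError):
    """Raised for ill-formed diabatic models (e.g. nonpositive frequencies)."""


class InvalidCompositionError(GCTetraError):
    """Raised when an adiabatic composition table is not normalized."""


class IntegrationFailure(GCTetraError):
    """Raised when total energy drifts beyond tolerance between hops."""


class UndefinedStateError(GCTetraError):
    """Raised when descriptors are requested for an all-zero transition density."""


class InvalidWeightsError(GCTetraError):
    """Raised for negative NTO amplitudes."""


class CapabilityError(GCTetraError):
    """A downstream stage requires a data channel the source did not provide."""


class MalformedTrajectoryError(GCTetraError):
    """Raised when on-disk trajectory files are inconsistent or truncated."""


class MissingFileError(GCTetraError):
    """Raised when a manifest references a file that does not exist."""


class DialectConfigError(GCTetraError):
    """Raised when an external-dialect mapping leaves required roles undeclared."""


class RegistryError(GCTetraError):
    """Raised for hydrogen-bond registries referencing invalid atoms."""


class UndefinedPermanenceError(GCTetraError):
    """Permanence is only defined for terminated trajectories."""


class UndefinedDecayError(GCTetraError):
    """Raised when no uncensored arrival time is available for the decay fit."""


class EmptyEnsembleError(GCTetraError):
    """Raised for operations that require at least one trajectory."""
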