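"""Exception hierarchy shared across the package."""


class QsdwkbError(Exception):
    """Base class for all package-specific errors."""


class ModelError(QsdwkbError):
    """The model specification is invalid (jump set, rate signs, parameters)."""


class DomainError(QsdwkbError):
    """A point lies outside the model's continuous or lattice state space."""


class NoEquilibrium(QsdwkbError):
    """Root-finding located no interior equilibrium of the drift field."""


class AssumptionViolation(QsdwkbError):
    """A standing model assumption fails; carries diagnostic data.

    ``self.spectrum`` holds the offending Jacobian eigenvalues when the
    violation concerns stability.
    """

    def __init__(self, message, spectrum=None):
        super().__init__(message)
        self.spectrum = spectrum


class CriteriaViolation(QsdwkbError):
    """An asymptotic reversibility criterion fails where a PASS is required."""


class DivergentAction(QsdwkbError):
    """The action integral to the requested endpoint does not converge."""


class Divergence(QsdwkbError):
    """The subleading correction diverges (point on the boundary)."""


class NotBirthDeath(ModelError):
    """Operation requires the multitype birth-death jump set {±e_i}."""


class Subcritical(QsdwkbError):
    """The linearised process at the origin is not supercritical."""


class AllCensored(QsdwkbError):
    """Censored-exponential MLE needs at least one observed event."""


class ProtocolError(QsdwkbError):
    """The simulation protocol could not be completed as specified."""


class NumericError(QsdwkbError):
    """A numerical routine failed (non-finite derivative, non-convergence)."""


class ResourceError(QsdwkbError):
    """A configured resource limit (state count) would be exceeded."""


class ConsistencyError(QsdwkbError):
    """Two routes to the same quantity disagree beyond tolerance."""


class ConfigError(QsdwkbError):
    """A run configuration failed schema validation."""
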