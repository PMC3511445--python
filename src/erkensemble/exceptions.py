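"""Exception hierarchy for the erkensemble pipeline.

Every stage raises a subclass of :class:`ErkEnsembleError`, so callers can
catch pipeline failures without masking programming errors.
"""


class ErkEnsembleError(Exception):
    """Base class for all erkensemble errors."""


class SchemaError(ErkEnsembleError):
    """A data file does not conform to the documented CSV schema."""


class ValidationError(ErkEnsembleError):
    """A dataset or parameter object violates an invariant."""


class InsufficientDataError(ErkEnsembleError):
    """Too few data points to perform a fit."""


class FittingError(ErkEnsembleError):
    """An optimization failed to converge from every starting point."""


class InitializationError(ErkEnsembleError):
    """No admissible pre-stimulus steady state could be located."""


class IntegrationError(ErkEnsembleError):
    """The ODE solver failed or produced an invalid trajectory."""


class SamplerError(ErkEnsembleError):
    """The Metropolis sampler hit a pathological regime (e.g. zero
    acceptance at the final temperature, or an acceptance rate too low to
    harvest an ensemble)."""


class InsufficientEnsembleError(ErkEnsembleError):
    """Ensemble statistics requested on fewer than two parameter sets."""
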