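"""Exception hierarchy. All pyrfate errors derive from PyrfateError."""


class PyrfateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PyrfateError):
    """Invalid model configuration: unknown states, bad schema, unknown regime."""


class InvalidRateError(PyrfateError, ValueError):
    """A rate is out of the domain the interpretation allows (e.g. hourly
    probability >= 1, or a per-source outgoing probability >= 1)."""


class ContractError(PyrfateError, ValueError):
    """A call violated an operation precondition (shape mismatch, bad argument)."""


class PartitionError(ConfigurationError):
    """Piecewise segments do not partition [0, inf) (gap or overlap)."""


class DecompositionError(PyrfateError):
    """Canonical (Q, R) decomposition undefined (no absorbing state)."""


class NoAbsorptionError(PyrfateError):
    """(I - Q) is singular: some transient state has no escape route."""


class NotEliminatedError(PyrfateError):
    """The medium never fell below the threshold within the horizon."""

    def __init__(self, state: str, final_level: float, threshold_mass: float):
        self.state = state
        self.final_level = final_level
        self.threshold_mass = threshold_mass
        super().__init__(
            f"{state!r} not eliminated within the horizon: final level "
            f"{final_level:.6g} >= threshold {threshold_mass:.6g}"
        )


class NothingAbsorbedError(PyrfateError):
    """Pathway fractions are undefined: no mass has been eliminated."""


class FitDomainError(PyrfateError):
    """Series cannot be log-transformed even after floor censoring."""
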