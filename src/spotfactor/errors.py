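"""Exception types shared across spotfactor modules."""


class SpotfactorError(Exception):
    """Base class for all spotfactor errors."""


class FormatError(SpotfactorError, ValueError):
    """A file or token does not conform to the documented text format."""


class ContractError(SpotfactorError, ValueError):
    """Arguments violate a documented precondition (shape, label, range)."""


class DegenerateDataError(SpotfactorError, ValueError):
    """Input data carry no information for the requested operation."""


class DegenerateAllocationError(SpotfactorError, ValueError):
    """A positive count must be allocated but every factor rate is zero."""


class NumericalError(SpotfactorError, RuntimeError):
    """A numerical failure (NaN/Inf) occurred; carries the sweep index."""

    def __init__(self, message: str, sweep: int | None = None):
        super().__init__(message)
        self.sweep = sweep


class ConfigurationError(SpotfactorError, ValueError):
    """Mutually inconsistent configuration options."""
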