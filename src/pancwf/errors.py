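"""Exception hierarchy for the demand/supply scenario model."""


class PancwfError(Exception):
    """Base class for all package errors."""


class ValidationError(PancwfError):
    """Input data or configuration violates a model invariant."""


class InsufficientDataError(PancwfError):
    """A trend fit was requested on fewer observations than required."""


class DegenerateFitError(PancwfError):
    """A trend fit cannot be identified (e.g. an all-zero count history)."""


class InfeasibleScenarioError(PancwfError):
    """A stage-shift scenario implies a negative early-stage cell.

    Raised when the retained stage-III and residual stage-IV cases exceed the
    conserved year total, so no non-negative stage I-II count exists.
    """
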