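"""Exception hierarchy for kinetic-modelling failures.

Errors are split by origin: bad measurements (:class:`InvalidSampleError`),
physically impossible prescriptions (:class:`InfeasiblePrescriptionError`),
numerical breakdown (:class:`IntegrationFailureError`), and missing or
insufficient data (:class:`MissingDataError`, :class:`UnderdeterminedError`).
"""


class PbutkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidSampleError(PbutkinError, ValueError):
    """A measured concentration or protein value violates its physical domain."""


class MeasurementInconsistencyError(InvalidSampleError):
    """Paired measurements imply a physically impossible quantity (e.g. K < 0)."""


class InfeasiblePrescriptionError(PbutkinError, ValueError):
    """A dialysis prescription cannot be run (e.g. ultrafiltration empties V1)."""


class IntegrationFailureError(PbutkinError, RuntimeError):
    """The ODE solver produced a non-finite state; carries the parameter set."""


class MissingDataError(PbutkinError, ValueError):
    """A required sample (site, time) is absent from the sample sheet."""


class UnderdeterminedError(PbutkinError, ValueError):
    """Fewer informative samples than free parameters."""


class NonConvergenceError(PbutkinError, RuntimeError):
    """Weekly simulation failed to reach steady state within the week budget."""


class SchemaError(PbutkinError, ValueError):
    """A sample-sheet file violates the CSV schema; message carries row numbers."""
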