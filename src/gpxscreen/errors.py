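"""Exception hierarchy for the screening pipeline.

Exit-code mapping used by the CLI: validation errors -> 2, QC gate -> 3,
anything else raised during a stage -> 4.
"""


class GpxScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(GpxScreenError):
    """A domain object or argument violates its contract."""


class PlateFormatError(ValidationError):
    """A tabular input is missing required columns or is otherwise malformed."""


class PlateIntegrityError(ValidationError):
    """Rows parse individually but contradict each other or plate geometry."""


class DataError(GpxScreenError):
    """A well lacks the reads an operation requires."""


class QCError(GpxScreenError):
    """Plate-level quality control cannot be computed or fails hard."""


class QCGateError(QCError):
    """Every plate failed QC; downstream stages refuse to run."""


class FitError(GpxScreenError):
    """Concentration-response fitting cannot proceed on the given series."""


class SimulationError(GpxScreenError):
    """The kinetic solver failed to produce a valid trajectory."""


class CapacityError(ValidationError):
    """Requested layout does not fit on the available plates."""


class TriageError(GpxScreenError):
    """Contradictory stage flags prevent a specificity call."""
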