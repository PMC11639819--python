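"""Exception hierarchy shared across the pipeline."""


class PedibcaError(Exception):
    """Base class for all package errors."""


class DomainError(PedibcaError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class DegenerateCalibrationError(DomainError):
    """Two-point load-cell calibration with coincident reference counts."""


class InvalidReadingError(PedibcaError, ValueError):
    """A sensor reading implies a physically impossible value (e.g. negative weight)."""


class InfiniteImpedanceError(DomainError):
    """Impedance sweep with zero voltage difference across the load."""


class ContractError(PedibcaError, ValueError):
    """A structural precondition on tabular input is violated."""


class EstimationStageError(PedibcaError, RuntimeError):
    """Failure in one stage of the estimation chain, labelled by stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class InversionError(PedibcaError, ValueError):
    """Composition outside the invertible domain of the sensor chain."""

    def __init__(self, quantity: str, message: str):
        self.quantity = quantity
        super().__init__(f"cannot invert {quantity}: {message}")


class SingularDesignError(PedibcaError, ValueError):
    """Rank-deficient or underdetermined regression design."""


class SpecError(PedibcaError, ValueError):
    """Invalid simulation specification."""


class SchemaError(PedibcaError, ValueError):
    """Malformed input table (missing or ill-typed columns)."""

    def __init__(self, message: str, columns=()):
        self.columns = list(columns)
        super().__init__(message)
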