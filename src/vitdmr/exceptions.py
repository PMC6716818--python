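"""Exception hierarchy shared across the pipeline stages."""


class VitdmrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VitdmrError, ValueError):
    """A scenario or model parameter is outside its valid domain."""


class AlignmentError(VitdmrError, ValueError):
    """Per-subject inputs are not aligned (mismatched lengths or indexes)."""


class SchemaError(VitdmrError, ValueError):
    """A cohort or results file violates the column contract."""


class SingularDesignError(VitdmrError, ValueError):
    """Design matrix is rank deficient after adding the intercept."""


class ConvergenceError(VitdmrError, RuntimeError):
    """An iterative fit failed to converge."""


class InsufficientInstrumentsError(VitdmrError, ValueError):
    """An estimator needs more instruments than were supplied."""


class UndefinedRatioError(VitdmrError, ZeroDivisionError):
    """Wald-type ratio requested with a zero gene-exposure coefficient."""
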