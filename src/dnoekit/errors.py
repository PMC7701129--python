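"""Exception hierarchy shared across the package."""


class DnoekitError(Exception):
    """Base class for all errors raised by dnoekit."""


class FormatError(DnoekitError):
    """A table or descriptor does not follow the expected format."""


class EmptyInputError(DnoekitError):
    """An input table contains no data rows."""


class InsufficientDataError(DnoekitError):
    """Too few observations for a stable estimate or fit."""


class IllPosedFitError(DnoekitError):
    """The normal equations of a least-squares problem are singular."""


class ConvergenceError(DnoekitError):
    """The optimizer did not converge within its iteration budget."""


class AlignmentError(DnoekitError):
    """Residue sets of two tables do not match."""


class MissingRateError(DnoekitError):
    """A required relaxation rate (e.g. per-residue R1N) is not available."""


class SingularCorrectionError(DnoekitError):
    """A correction formula denominator is numerically zero."""


class UndefinedNOEError(DnoekitError):
    """The reference intensity is zero, so epsilon = S_sat/S_ref is undefined."""
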