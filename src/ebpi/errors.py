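"""Exception and warning hierarchy."""


class EBPIError(Exception):
    """Base class for all package errors."""


class DataError(EBPIError):
    """Invalid or inconsistent input data (CLI exit code 1)."""


class ZeroCellError(DataError):
    """A 2x2 table cell is zero and no continuity correction was requested."""


class EstimationError(EBPIError):
    """A model fit failed (separation, non-convergence, no information)."""


class EBPIWarning(UserWarning):
    """Base class for all package warnings."""


class SmallPanelWarning(EBPIWarning):
    """Panel size below the recommended minimum for nominal PI coverage."""


class DegeneratePriorWarning(EBPIWarning):
    """Prior variance estimate truncated to zero; prediction intervals collapse."""
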