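"""Exception hierarchy shared by all modules."""


class SlleSc2Error(Exception):
    """Base class for package errors."""


class DataValidationError(SlleSc2Error):
    """Input data violates a structural or numeric contract."""


class ParameterError(SlleSc2Error):
    """A user-supplied parameter is out of its legal range."""


class NumericalError(SlleSc2Error):
    """A numerical procedure failed (singular system, no convergence)."""
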