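"""Exception hierarchy.

``ValidationError`` covers malformed or out-of-contract inputs (exit code 1
at the CLI boundary); everything unexpected is an internal error (exit 2).
"""


class IapflowError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(IapflowError):
    """Input violates a documented precondition (bad file, bad value, bad layout)."""


class CalibrationError(IapflowError):
    """Calibration standards cannot yield a monotone optical-density -> activity map."""


class CalibrationRangeError(CalibrationError):
    """A queried optical density falls outside the trusted range of the standards."""


class NonIdentifiableError(IapflowError):
    """A tissue concentration has no admissible flow under the kinetic model."""


class GeneratorError(IapflowError):
    """The synthetic-study generator was configured outside its own valid regime."""
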