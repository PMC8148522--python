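"""Package exception types.

``MethodUnavailableError`` signals that a reconstruction formula cannot be
applied to the data at hand (e.g. the current-weighted density method when
no crossing events were observed in one direction); it maps to CLI exit
code 3.  ``NumericalBreakdownError`` signals a reconstruction that produced
non-physical intermediate values (e.g. a non-positive current ratio far
from the reference voltage); it maps to CLI exit code 4.
"""


class EdChannelError(Exception):
    """Base class for package errors."""


class DiscretizationError(EdChannelError, ValueError):
    """Time step or binning unsafe for the requested simulation."""


class CalibrationError(EdChannelError, RuntimeError):
    """Detailed-balance calibration could not be established."""


class MethodUnavailableError(EdChannelError, RuntimeError):
    """A reconstruction method cannot be applied to the given statistics."""


class NumericalBreakdownError(EdChannelError, RuntimeError):
    """A reconstruction produced non-physical intermediate values."""
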