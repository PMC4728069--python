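"""Exception hierarchy.

Everything derives from :class:`WPDenoiseError` so callers can catch the
package's failures with a single ``except``; most also derive from
:class:`ValueError` because they signal invalid arguments or inputs.
"""


class WPDenoiseError(Exception):
    """Base class for all errors raised by wpdenoise."""


class ParameterError(WPDenoiseError, ValueError):
    """An argument is outside its valid range."""


class UnsupportedWaveletError(WPDenoiseError, ValueError):
    """The requested wavelet name is not in the supported set."""


class DepthError(WPDenoiseError, ValueError):
    """The signal is too short for the requested decomposition depth."""


class DegenerateInputError(WPDenoiseError, ValueError):
    """The input makes the requested quantity undefined (e.g. constant
    signal for a correlation, zero-RMS signal for noise scaling)."""


class CorruptTreeError(WPDenoiseError, ValueError):
    """A wavelet-packet tree is incomplete or internally inconsistent."""


class FilterDesignError(WPDenoiseError, ValueError):
    """A filter specification cannot be realised at the given sample rate."""


class AnnotationError(WPDenoiseError, ValueError):
    """Segment labels are missing, malformed or inconsistent."""


class DegenerateMetricError(WPDenoiseError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero noise power)."""


class FormatError(WPDenoiseError, ValueError):
    """An audio or label file could not be parsed."""
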