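"""Exception hierarchy shared across the pipeline."""


class CogVergenceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CogVergenceError):
    """A file does not conform to the documented CSV/YAML layout."""


class DataError(CogVergenceError):
    """A file is well-formed but its contents violate an invariant."""


class ParameterError(CogVergenceError):
    """Invalid simulation or analysis parameters."""


class WindowError(CogVergenceError):
    """An analysis window does not intersect the sample grid."""


class AlignmentError(CogVergenceError):
    """Curves that must share a time grid do not."""


class ReportError(CogVergenceError):
    """A results directory is missing a file the report needs."""
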