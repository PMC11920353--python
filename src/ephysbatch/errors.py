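"""Exception hierarchy.

All analysis failures derive from :class:`AnalysisError` so the batch driver can
isolate them per recording or per output without masking programming errors.
"""


class AnalysisError(Exception):
    """Base class for recoverable analysis failures."""


class WindowError(AnalysisError):
    """A protocol window falls outside the recorded trace."""


class BaseUndefinedError(WindowError):
    """No pre-stimulus samples exist (protocol starts at t = 0)."""


class ConfigError(AnalysisError):
    """Invalid analysis configuration (channels, names, selections)."""


class ChannelError(AnalysisError):
    """A requested channel index does not exist in a file."""


class FormatError(AnalysisError):
    """A file could not be parsed as a supported recording format."""


class FitError(AnalysisError):
    """An exponential fit failed to converge or produced a non-physical value."""
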