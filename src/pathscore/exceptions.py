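"""Exception hierarchy shared across the package."""


class PathscoreError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PathscoreError, ValueError):
    """An invalid parameter value (simulation or dose model)."""


class FormatError(PathscoreError, ValueError):
    """An input file does not match the expected format."""


class SplitError(PathscoreError, ValueError):
    """A dataset cannot be split as requested."""


class DataError(PathscoreError, ValueError):
    """Empty or degenerate data where a computation needs observations."""


class ConfigurationError(PathscoreError, ValueError):
    """Inconsistent model/weights/head configuration."""
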