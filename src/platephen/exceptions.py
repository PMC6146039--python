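"""Exception hierarchy shared by all platephen modules."""


class PlatephenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlatephenError):
    """A file exists but does not match the expected format/dialect."""


class ParameterError(PlatephenError):
    """An algorithm parameter is outside its valid domain."""


class DataAlignmentError(PlatephenError):
    """Two data streams that must share a well set do not."""


class EstimationError(PlatephenError):
    """Not enough usable data to estimate a quantity."""


class AnalysisError(PlatephenError):
    """A computation was requested on degenerate or invalid data."""


class ScenarioError(PlatephenError):
    """A synthetic-data scenario is internally inconsistent."""


class ConfigError(PlatephenError):
    """A run configuration is invalid or references missing inputs."""
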