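"""Exception hierarchy used across the pipeline stages."""


class BurstlabError(Exception):
    """Base class for all burstlab errors."""


class FormatError(BurstlabError):
    """A raw input file could not be parsed (names the offending line)."""


class EmptyInputError(BurstlabError):
    """An input file or record collection contained no usable data."""


class ConfigurationError(BurstlabError):
    """A dialect or run configuration is incomplete or inconsistent."""


class ConsistencyError(BurstlabError):
    """Inputs contradict each other (e.g. events after the declared dataset end)."""


class InvalidParameterError(BurstlabError, ValueError):
    """A parameter is outside its documented domain."""


class InsufficientDataError(BurstlabError):
    """Too few observations to carry out the requested computation."""


class DegenerateSampleError(BurstlabError):
    """A sample is degenerate for the requested estimator (e.g. zero variance)."""
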