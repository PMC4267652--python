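"""Exception hierarchy shared across the pipeline."""


class ChromnetError(Exception):
    """Base class for all chromnet errors."""


class ParameterError(ChromnetError, ValueError):
    """Invalid simulation or analysis parameters."""


class SchemaError(ChromnetError, ValueError):
    """Track names, roles or matrix shapes do not line up."""


class StateError(ChromnetError, ValueError):
    """A matrix operation was called out of pipeline order."""


class DegenerateTrackError(ChromnetError, ValueError):
    """A track is constant where variation is required."""


class DataError(ChromnetError, ValueError):
    """Non-finite or otherwise unusable numeric input."""
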