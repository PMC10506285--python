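"""Exception hierarchy shared across the pipeline."""


class SpotlinkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SpotlinkError):
    """A file on disk does not conform to its declared format."""


class ValidationError(SpotlinkError):
    """An in-memory object violates a structural invariant."""


class ParameterError(SpotlinkError):
    """A configuration or generator parameter is out of its valid range."""
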