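"""Exception hierarchy shared across the pipeline stages."""


class HistoscoreError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HistoscoreError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(HistoscoreError):
    """A path, folder layout or config file does not match expectations."""


class EmptyGridError(HistoscoreError):
    """A slide is too small to yield a single tile."""


class DegenerateVectorError(HistoscoreError):
    """A probability vector carries no mass on the score classes."""


class BackboneUnavailableError(HistoscoreError):
    """The pretrained transfer backbone cannot be loaded in this environment."""


class ModelFormatError(HistoscoreError):
    """A model archive is corrupt or from an incompatible version."""
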