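"""Exception hierarchy shared across the package."""


class RifiberError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RifiberError, ValueError):
    """An object or parameter violates a documented invariant."""


class MetadataError(RifiberError):
    """Required physical metadata is missing or unparseable."""


class FormatError(RifiberError):
    """An image stack is malformed (mixed dtypes, inconsistent pages, ...)."""


class FitError(RifiberError):
    """A model fit failed to converge; carries diagnostics in ``args``."""
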