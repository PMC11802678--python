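"""Exception hierarchy shared by all pipeline stages."""


class OxstabError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(OxstabError):
    """Input violates a schema or type invariant."""


class InvalidMeasurementError(ValidationError):
    """A conductivity measurement cannot yield an injury index."""


class InsufficientDataError(OxstabError):
    """Too few points for the requested fit."""


class DomainError(OxstabError):
    """Values outside the mathematical domain of an operation."""


class CoverageError(OxstabError):
    """Time series does not cover the required period densely enough."""


class NoRootError(OxstabError):
    """The fitted dose-response curve never crosses the threshold."""
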