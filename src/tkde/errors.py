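"""Exception hierarchy shared across the package."""


class TkdeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TkdeError):
    """A file does not conform to its expected tabular format."""


class ValidationError(TkdeError):
    """Parsed content violates a semantic invariant (duplicate ids, unknown keys...)."""


class ParameterError(TkdeError):
    """A user-supplied parameter is outside its legal range."""


class ConfigurationError(TkdeError):
    """A simulation or run configuration is internally inconsistent or infeasible."""
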