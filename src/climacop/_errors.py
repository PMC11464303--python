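"""Exception hierarchy shared across the package."""


class ClimacopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClimacopError):
    """A config file, spec, or parameter is malformed or inconsistent (exit code 2)."""


class DataError(ClimacopError):
    """Input data violates a precondition of an operation (exit code 3)."""
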