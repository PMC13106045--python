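"""Exception hierarchy shared across the package."""


class FortisimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FortisimError, ValueError):
    """A distribution, scenario or cost parameter violates its contract."""


class ConfigurationError(FortisimError):
    """An input table or configuration is internally inconsistent or incomplete."""


class IntegrityError(FortisimError):
    """Two tables that must describe the same strata universe disagree."""


class NumericalError(FortisimError):
    """A quadrature or root-finding step failed to converge."""
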