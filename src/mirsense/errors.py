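"""Exception hierarchy shared across the package."""


class MirsenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MirsenseError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(MirsenseError, ValueError):
    """A configuration object or file is invalid or incomplete."""


class DegenerateFitError(MirsenseError):
    """Curve fitting was requested on data that cannot constrain the model."""


class NoCrossingError(MirsenseError):
    """A dose-response curve never crosses the requested threshold."""


class DataCompletenessError(MirsenseError):
    """A screen table is missing records required by an operation."""


class LayoutError(MirsenseError):
    """Plate-layout bookkeeping is inconsistent (missing/duplicate wells)."""


class UnknownVariantError(MirsenseError, KeyError):
    """A composition references a component variant absent from the library."""


class NarrowRangeWarning(UserWarning):
    """An optimum was found on the boundary of the searched range."""
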