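"""Exception hierarchy shared across the package."""


class RamanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RamanError, ValueError):
    """A text spectrum file could not be parsed."""


class ValidationError(RamanError, ValueError):
    """An object violates one of its structural invariants."""


class AssemblyError(RamanError, ValueError):
    """Spectra cannot be assembled onto a common wavenumber grid."""


class IntegrityError(RamanError, ValueError):
    """Matrix and metadata are mutually inconsistent."""


class ParameterError(RamanError, ValueError):
    """A numeric parameter is out of its admissible range."""


class DegenerateInputError(RamanError, ValueError):
    """The input is too degenerate for the requested computation."""


class UndefinedMetricError(RamanError, ZeroDivisionError):
    """A classification metric has an empty margin."""


class MissingLabelError(RamanError, KeyError):
    """A required component label is absent from an annotation."""


class InvalidModelError(RamanError, ValueError):
    """A fitted model is unusable for prediction (e.g. non-positive slope)."""
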