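"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`HdospecError`
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class HdospecError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(HdospecError, ValueError):
    """A spectrum file could not be parsed; message names the offending line."""


class DuplicateAbscissaError(SpectrumParseError):
    """Two rows share the same wavenumber."""


class GridMismatchError(HdospecError, ValueError):
    """An operation required spectra on one common grid."""


class UnitMismatchError(HdospecError, ValueError):
    """Absorbance and molar-absorption spectra were mixed without conversion."""


class SpectralRangeError(HdospecError, ValueError):
    """A requested window or target grid falls outside the data span."""


class DomainError(HdospecError, ValueError):
    """A physical parameter is outside its admissible domain."""


class EstimationError(HdospecError, RuntimeError):
    """A fit or estimate is not identifiable from the given data."""


class ConvergenceError(HdospecError, RuntimeError):
    """An iterative fit exhausted its budget.

    The best solution reached so far is attached as ``best`` when available.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class GenerationError(HdospecError, ValueError):
    """A synthetic fixture cannot be realised with the requested parameters."""


class StructureParseError(HdospecError, ValueError):
    """A coordinate file could not be parsed; message names the offending line."""


class ConfigError(HdospecError, ValueError):
    """A manifest or run configuration failed validation."""
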