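"""Exception hierarchy shared across the package."""


class AquanirError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AquanirError):
    """A file does not follow the expected wide-CSV layout."""


class GridError(AquanirError):
    """Wavelength axis is missing, unordered or not evenly spaced."""


class ParameterError(AquanirError):
    """An operation received an invalid parameter."""


class DegenerateDataError(AquanirError):
    """The data cannot support the requested operation (constant rows, single class, ...)."""


class DimensionError(AquanirError):
    """Array shapes or wavelength grids do not match."""


class RangeError(AquanirError):
    """A wavelength window does not overlap the grid."""


class StratificationError(AquanirError):
    """Cross-validation folds cannot be built with every class in every training set."""


class CoverageError(AquanirError):
    """A requested wavelength is not covered by the (possibly truncated) grid."""
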