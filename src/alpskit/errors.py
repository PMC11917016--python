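"""Exception and warning types shared across the package."""


class AlpskitError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(AlpskitError):
    """A configuration object violates its invariants."""


class InsufficientDesignError(AlpskitError):
    """Gradient scheme or statistical design cannot support the requested fit."""


class GeometryError(AlpskitError):
    """Affine or spatial transform is unusable (e.g. singular)."""


class PlacementError(AlpskitError):
    """A lesion or ROI falls outside the volume it must live in."""


class SpecificationError(AlpskitError):
    """An ROI set is incomplete or inconsistent."""


class UndefinedIndexError(AlpskitError):
    """The ALPS ratio is undefined (non-positive denominator)."""


class DataValidationError(AlpskitError):
    """Input data violates a documented range or shape constraint."""


class EmptyRoiWarning(UserWarning):
    """An ROI sphere intersects no voxel centers."""


class CollinearityWarning(UserWarning):
    """Regression design matrix is ill-conditioned."""
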