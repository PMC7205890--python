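"""Exception hierarchy shared across the toolkit."""


class CineStrainError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(CineStrainError):
    """Contours or boundary masks violate a geometric precondition."""


class DegenerateDomainError(CineStrainError):
    """The region between the boundaries is empty (nothing to solve on)."""


class TracingStalledError(CineStrainError):
    """A streamline stopped moving before reaching the far boundary."""


class GapError(CineStrainError):
    """A frame required for tracking is missing; no interpolation is done."""


class DegenerateConfigurationError(CineStrainError):
    """A local point configuration is collinear/degenerate for strain."""


class UndefinedTermError(CineStrainError):
    """A statistic has a zero denominator (e.g. single-class ground truth)."""


class InvalidWeightsError(CineStrainError):
    """Loss weights do not satisfy alpha + beta = 1 with both nonnegative."""


class GeometryOverflowError(CineStrainError):
    """Phantom motion would push the myocardium outside the image."""
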