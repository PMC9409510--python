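"""Exception types shared across the package."""


class RadibiasError(Exception):
    """Base class for package errors."""


class GeometryError(RadibiasError):
    """Volumes/masks do not share grid shape or spacing."""


class SizingError(RadibiasError):
    """Phantom grid too small to contain the requested inserts."""


class DegenerateROIError(RadibiasError):
    """ROI empty or too small for the requested operation."""


class DegenerateFeatureError(RadibiasError):
    """A statistic is undefined for the given values (e.g. zero variance)."""
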