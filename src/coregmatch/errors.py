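"""Exception types shared across the toolkit."""


class CoregError(Exception):
    """Base class for all toolkit errors."""


class InsufficientDataError(CoregError):
    """Too few points for the requested model."""


class DegenerateGeometryError(CoregError):
    """Point configuration does not determine the model (coplanar, collinear, duplicated)."""


class BinningError(CoregError):
    """A z bin is empty even after fallback widening."""


class InversionError(CoregError):
    """Fixed-point inversion failed to converge for some points."""

    def __init__(self, message, indices=None):
        super().__init__(message)
        self.indices = [] if indices is None else list(indices)


class SchemaError(CoregError):
    """A table does not match its declared schema."""


class VolumeError(CoregError):
    """A voxel volume is unusable for the requested operation."""


class ExtrapolationWarning(UserWarning):
    """Points evaluated outside the fitted bounding box."""
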