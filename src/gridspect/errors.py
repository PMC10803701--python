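"""Exception hierarchy shared across gridspect modules."""


class GridspectError(Exception):
    """Base class for all gridspect errors."""


class InvalidParameterError(GridspectError, ValueError):
    """A scalar parameter is outside its valid domain."""


class SamplingError(GridspectError, ValueError):
    """Voxel size too coarse to resolve the requested structure."""


class GeometryError(GridspectError, ValueError):
    """Inconsistent or impossible geometric configuration."""


class EmptyGeometryError(GeometryError):
    """An operation received geometry with no voxels/solids to act on."""


class ShapeMismatchError(GridspectError, ValueError):
    """Two lattices expected to be congruent are not."""


class ConfigError(GridspectError, ValueError):
    """Invalid acquisition/reconstruction/experiment configuration."""


class FitError(GridspectError, RuntimeError):
    """A model fit failed to converge or is degenerate."""


class UnitError(GridspectError, ValueError):
    """Missing or inconsistent physical units (e.g. no calibration factor)."""
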