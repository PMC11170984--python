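"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, everything else
raised by pipeline stages -> 3.
"""


class MemlocError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MemlocError):
    """Invalid or incomplete configuration."""


class DataError(MemlocError):
    """Malformed or inconsistent input data (images, ROIs, tables)."""


class GeometryError(MemlocError):
    """Polygon or ray-geometry failure (degenerate/non-star-shaped ROI...)."""


class PlacementError(MemlocError):
    """Rejection sampling could not place all cells on the canvas."""
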