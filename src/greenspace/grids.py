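"""Planar raster grid geometry.

All spatial data in this package live in a single planar Cartesian
coordinate system with meter units (tagged ``local-meters``). A grid is
anchored at its top-left corner; row indices increase downward (decreasing
y), column indices increase rightward (increasing x), the convention used
by north-up GeoTIFFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: CRS tag written into every file this package produces.
CRS_TAG = "local-meters"


@dataclass(frozen=True)
class RasterGrid:
    """Geometry of a regular square-pixel raster.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates (meters) of the grid's top-left corner.
    pixel_size
        Side length of a pixel in meters (> 0).
    n_rows, n_cols
        Raster shape.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size

    def window(
        self, bounds: tuple[float, float, float, float]
    ) -> tuple[slice, slice]:
        """Row/column slices of pixels whose centers may fall in ``bounds``.

        The window is clamped to the grid; it may be empty.
        """
        minx, miny, maxx, maxy = bounds
        c0 = int(np.floor((minx - self.origin_x) / self.pixel_size - 0.5)) + 1
        c1 = int(np.ceil((maxx - self.origin_x) / self.pixel_size - 0.5)) + 1
        r0 = int(np.floor((self.origin_y - maxy) / self.pixel_size - 0.5)) + 1
        r1 = int(np.ceil((self.origin_y - miny) / self.pixel_size - 0.5)) + 1
        r0, r1 = max(r0, 0), min(r1, self.n_rows)
        c0, c1 = max(c0, 0), min(c1, self.n_cols)
        return slice(r0, max(r0, r1)), slice(c0, max(c0, c1))

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "crs": CRS_TAG,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RasterGrid":
        crs = d.get("crs", CRS_TAG)
        if crs != CRS_TAG:
            raise ValueError(f"unsupported CRS tag {crs!r}; expected {CRS_TAG!r}")
        return cls(
            origin_x=float(d["origin_x"]),
            origin_y=float(d["origin_y"]),
            pixel_size=float(d["pixel_size"]),
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
        )
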