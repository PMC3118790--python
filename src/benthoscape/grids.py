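"""Lightweight raster containers shared across pipeline stages.

Coordinate convention (used everywhere in the package): cell-centre
registration, easting/northing in metres, row 0 is the northern edge of the
grid and the origin (x0, y0) is the south-west corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RasterGrid:
    """A single-band raster of float values on a regular 2 m-style grid."""

    values: np.ndarray
    cell_size: float = 2.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Easting/northing of the centre of cell (row, col)."""
        nrows = self.values.shape[0]
        e = self.x0 + (col + 0.5) * self.cell_size
        n = self.y0 + (nrows - row - 0.5) * self.cell_size
        return e, n

    def cell_of(self, easting: float, northing: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (inverse of cell_center)."""
        nrows = self.values.shape[0]
        col = int(np.floor((easting - self.x0) / self.cell_size))
        row = int(nrows - 1 - np.floor((northing - self.y0) / self.cell_size))
        return row, col


@dataclass
class CategoricalRaster:
    """An integer-coded thematic raster with a legend.

    Cells with code ``NODATA`` (-1) are treated as missing throughout.
    """

    codes: np.ndarray
    legend: tuple[str, ...]
    cell_size: float = 2.0
    x0: float = 0.0
    y0: float = 0.0

    NODATA: int = field(default=-1, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.ndim != 2:
            raise ValueError("CategoricalRaster codes must be 2-D")
        valid = self.codes[self.codes != self.NODATA]
        if valid.size and (valid.min() < 0 or valid.max() >= len(self.legend)):
            raise ValueError("codes outside legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def n_classes(self) -> int:
        return len(self.legend)
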