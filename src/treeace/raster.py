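"""Canopy height model rasters and TIFF I/O.

Rasters use 0-based (row, col) indexing with row 0 at the north/top edge;
the cell (i, j) covers x in [origin_x + j*cs, origin_x + (j+1)*cs) and
y in (origin_y - (i+1)*cs, origin_y - i*cs], with the origin at the outer
corner of cell (0, 0). Cell centres are at offsets of (index + 0.5) * cs.

Files are single-band float32 TIFFs; origin, cell size and nodata are
stored as JSON in the ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["CHMRaster", "NODATA"]

NODATA = -9999.0


@dataclass
class CHMRaster:
    """Canopy height raster (metres above ground)."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CHM values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask(self) -> np.ndarray:
        """True for valid (non-nodata) cells."""
        return self.values != self.nodata

    def xy_to_rc(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map map-coordinates to (row, col) indices."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def rc_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre map coordinates for (row, col)."""
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def write(self, path: str) -> None:
        meta = {"cell_size": self.cell_size, "origin": list(self.origin),
                "nodata": self.nodata}
        arr = self.values.astype(np.float32)
        tifffile.imwrite(path, arr, description=json.dumps(meta))

    @classmethod
    def read(cls, path: str) -> "CHMRaster":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray().astype(float)
            desc = tf.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        return cls(values=arr,
                   cell_size=float(meta.get("cell_size", 1.0)),
                   origin=tuple(meta.get("origin", (0.0, 0.0))),
                   nodata=float(meta.get("nodata", NODATA)))


def write_labels(path: str, labels: np.ndarray, cell_size: float,
                 origin: tuple[float, float]) -> None:
    """Write an integer segment-label raster as int32 TIFF."""
    meta = {"cell_size": cell_size, "origin": list(origin), "nodata": 0}
    tifffile.imwrite(path, labels.astype(np.int32), description=json.dumps(meta))


def read_labels(path: str) -> tuple[np.ndarray, float, tuple[float, float]]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray().astype(int)
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return arr, float(meta.get("cell_size", 1.0)), tuple(meta.get("origin", (0.0, 0.0)))
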