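"""Raster mask -> shapely polygon conversion.

Cell-aligned and exact: each true cell contributes its square footprint and
the squares are unioned, so areas equal cell counts times cell area.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import GridRaster


def mask_to_polygon(mask: np.ndarray, grid: GridRaster) -> BaseGeometry:
    """Union of the square footprints of the true cells of ``mask``."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return shapely.Polygon()
    cs = grid.cell_size
    x0, y0 = grid.origin
    xmin = x0 + cols * cs
    xmax = xmin + cs
    ymax = y0 - rows * cs
    ymin = ymax - cs
    boxes = shapely.box(xmin, ymin, xmax, ymax)
    return shapely.union_all(boxes)
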