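"""Raster grid container and alignment.

The whole pipeline trades in :class:`GridRaster`: a single-band raster with
cell-centre semantics, (row, col) indexing with row 0 at the north edge, and
all distances expressed in metres of a projected CRS.  A set of mutually
aligned named rasters is a :class:`FactorStack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for malformed rasters or incompatible grids."""


@dataclass
class GridRaster:
    """A single-band georeferenced raster.

    Parameters
    ----------
    values
        2D array, row-major with row 0 at the northern edge.  Cell centres
        carry the values.
    cell_size
        Edge length of a (square) cell in metres of the projected CRS.
    origin
        (x, y) of the north-west *corner* of the grid in CRS coordinates.
    crs
        CRS identifier, e.g. ``"EPSG:32648"``.
    nodata
        Sentinel value excluded from all statistics, or ``None``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridError("raster values must be a non-empty 2D array")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    # -- nodata handling ------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        mask = np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask

    def finite_values(self) -> np.ndarray:
        """1D array of the valid cell values."""
        return self.values[self.valid_mask()]

    # -- derivation helpers ---------------------------------------------
    def like(self, values: np.ndarray, nodata: float | None = None) -> "GridRaster":
        """A new raster on this grid carrying ``values``."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise GridError(
                f"values shape {values.shape} does not match grid {self.shape}"
            )
        return GridRaster(values, self.cell_size, self.origin, self.crs, nodata)

    def copy(self) -> "GridRaster":
        return replace(self, values=self.values.copy())

    def same_grid(self, other: "GridRaster", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-6)
            and self.crs == other.crs
        )


def check_aligned(*rasters: GridRaster) -> None:
    """Raise :class:`GridError` unless every raster shares the first's grid."""
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_grid(r):
            raise GridError(
                f"rasters are not aligned: {ref.shape}@{ref.origin} vs "
                f"{r.shape}@{r.origin}"
            )


@dataclass
class FactorStack:
    """Named mapping of mutually aligned rasters."""

    layers: dict[str, GridRaster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        if rasters:
            check_aligned(*rasters)

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> GridRaster:
        return next(iter(self.layers.values()))

    def valid_mask(self) -> np.ndarray:
        """Cells valid in *every* layer: nodata anywhere poisons the stack."""
        mask = np.ones(self.reference.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid_mask()
        return mask

    def add(self, name: str, raster: GridRaster) -> None:
        if self.layers:
            check_aligned(self.reference, raster)
        if name in self.layers:
            raise GridError(f"duplicate layer name {name!r}")
        self.layers[name] = raster


def _overlap(a: GridRaster, b: GridRaster) -> bool:
    ax0, ay0, ax1, ay1 = a.bounds
    bx0, by0, bx1, by1 = b.bounds
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def align_stack(
    rasters: Mapping[str, GridRaster],
    reference: str | None = None,
    categorical: set[str] | frozenset[str] = frozenset(),
) -> FactorStack:
    """Resample every raster onto the grid of a reference layer.

    Categorical layers are resampled nearest-neighbour (no new class values
    can appear); continuous layers bilinear.  All inputs must share a CRS —
    reprojection between CRSs is out of scope.  Aligning an already aligned
    stack returns the inputs unchanged (idempotence).
    """
    if not rasters:
        raise GridError("align_stack requires at least one raster")
    names = list(rasters)
    ref_name = reference if reference is not None else names[0]
    if ref_name not in rasters:
        raise GridError(f"reference layer {ref_name!r} not among inputs")
    ref = rasters[ref_name]

    crss = {r.crs for r in rasters.values()}
    if len(crss) > 1:
        raise GridError(
            f"rasters carry different CRSs {sorted(map(str, crss))}; "
            "reproject to a common CRS first"
        )

    out: dict[str, GridRaster] = {}
    for name in names:
        src = rasters[name]
        if src.same_grid(ref):
            out[name] = src
            continue
        if not _overlap(src, ref):
            raise GridError(f"layer {name!r} has no spatial overlap with the reference")
        # fractional source indices of every reference cell centre
        rows = np.arange(ref.shape[0])
        cols = np.arange(ref.shape[1])
        xs = ref.origin[0] + (cols + 0.5) * ref.cell_size
        ys = ref.origin[1] - (rows + 0.5) * ref.cell_size
        src_c = (xs - src.origin[0]) / src.cell_size - 0.5
        src_r = (src.origin[1] - ys) / src.cell_size - 0.5
        rr, cc = np.meshgrid(src_r, src_c, indexing="ij")
        order = 0 if name in categorical else 1
        vals = src.values.astype(float)
        fill = src.nodata if src.nodata is not None else np.nan
        resampled = ndimage.map_coordinates(
            vals, [rr, cc], order=order, mode="constant", cval=fill
        )
        if order == 0 and np.issubdtype(src.values.dtype, np.integer):
            resampled = resampled.astype(src.values.dtype)
        out[name] = GridRaster(resampled, ref.cell_size, ref.origin, ref.crs, src.nodata)
    return FactorStack(out)
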