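"""Ecological source identification.

Sources are the habitat patches that supply the dominant ecosystem
services.  The pipeline takes the top-20% cells of each service raster,
counts per cell how many services select it (service richness), runs
Getis-Ord Gi* hot-spot analysis on that merged surface, and keeps the
8-connected significant clusters above a minimum area as the ecological
sources whose centre points serve as corridor terminals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .grid import GridRaster, check_aligned
from .vectorize import mask_to_polygon

#: Minimum patch area retained as a source (km²); patches smaller than
#: this are treated as scattered fragments and dropped.
DEFAULT_MIN_AREA_KM2 = 6.26

#: Hot-spot significance threshold on the Gi* z-score (90% confidence).
DEFAULT_Z_THRESHOLD = 1.65


@dataclass
class SourcePatch:
    id: int
    polygon: BaseGeometry
    area_km2: float
    centre: tuple[float, float]  # (x, y) terminal for corridor analysis
    centre_cell: tuple[int, int]  # (row, col)
    dominant_service_count: int = 0
    cells: np.ndarray | None = None  # (N, 2) array of (row, col) member cells


@dataclass
class SourceSet:
    patches: list[SourcePatch] = field(default_factory=list)
    grid: GridRaster | None = None  # template grid the patches live on

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    @property
    def total_area_km2(self) -> float:
        return float(sum(p.area_km2 for p in self.patches))

    def terminals(self) -> list[tuple[int, int]]:
        """(row, col) centre cells, the ant start/end points."""
        return [p.centre_cell for p in self.patches]

    def to_features(self) -> list[dict]:
        return [
            {
                "geometry": p.polygon,
                "properties": {
                    "id": p.id,
                    "area_km2": p.area_km2,
                    "dominant_service_count": p.dominant_service_count,
                    "centre_x": p.centre[0],
                    "centre_y": p.centre[1],
                },
            }
            for p in self.patches
        ]


def top_quantile_mask(service: GridRaster, q: float = 0.20) -> GridRaster:
    """Cells at or above the (1 − q) quantile of the service values.

    The selected fraction equals q up to one tie group; a constant raster
    is one tie group, so every cell is selected.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile proportion must be in (0, 1), got {q}")
    finite = service.finite_values()
    if finite.size == 0:
        raise ValueError("service raster has no finite cells")
    cutoff = np.quantile(finite, 1.0 - q)
    mask = service.valid_mask() & (
        np.nan_to_num(service.values.astype(float), nan=-np.inf) >= cutoff
    )
    return service.like(mask.astype(np.uint8))


def service_richness(masks: list[GridRaster]) -> GridRaster:
    """Per-cell count of services whose top-quantile mask selects the cell."""
    if not masks:
        raise ValueError("need at least one service mask")
    check_aligned(*masks)
    count = np.zeros(masks[0].shape, dtype=np.int16)
    for m in masks:
        count += m.values.astype(bool)
    return masks[0].like(count)


def _distance_band_footprint(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_cells**2 + 1e-9


def gi_star(fieldr: GridRaster, neighborhood_radius: float) -> GridRaster:
    """Getis-Ord Gi* z-scores with binary distance-band weights incl. self.

    For cell i with weights w_ij = 1 where d(i, j) ≤ radius:

        Gi* = (Σ w x_j − x̄ W_i) / (S √((n W_i − W_i²)/(n − 1)))

    with W_i = Σ w_ij, x̄ and S the global mean and population standard
    deviation over the n valid cells.  Positive z marks hot spots.
    """
    if neighborhood_radius < fieldr.cell_size:
        raise ValueError("neighborhood radius must be at least one cell")
    valid = fieldr.valid_mask()
    x = np.where(valid, fieldr.values.astype(float), 0.0)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need at least two valid cells")
    mean = x[valid].mean() if n else 0.0
    s = np.sqrt(np.mean(x[valid] ** 2) - mean**2)
    if s == 0:
        raise ValueError("zero variance: Gi* undefined on a constant field")
    fp = _distance_band_footprint(neighborhood_radius / fieldr.cell_size)
    wx = ndimage.convolve(x, fp.astype(float), mode="constant", cval=0.0)
    wi = ndimage.convolve(valid.astype(float), fp.astype(float), mode="constant")
    denom = s * np.sqrt(np.maximum(n * wi - wi**2, 0.0) / (n - 1))
    z = np.where(valid & (denom > 0), (wx - mean * wi) / np.where(denom > 0, denom, 1.0), np.nan)
    return fieldr.like(z)


def extract_source_patches(
    z: GridRaster,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    min_area_km2: float = DEFAULT_MIN_AREA_KM2,
    richness: GridRaster | None = None,
) -> SourceSet:
    """Significant hot-spot clusters above the minimum area, as sources.

    8-connected components of cells with z ≥ z_threshold are polygonized;
    components with area strictly below ``min_area_km2`` are dropped
    (patches *at* the threshold are retained).  Each source's centre is the
    cell of maximal z (ties broken toward the component centroid), its
    dominant_service_count the maximum of ``richness`` over the patch.
    """
    if not min_area_km2 > 0:
        raise ValueError("min_area_km2 must be positive")
    hot = z.valid_mask() & (np.nan_to_num(z.values.astype(float), nan=-np.inf) >= z_threshold)
    if not hot.any():
        warnings.warn("no cell passes the hot-spot threshold; empty source set",
                      stacklevel=2)
        return SourceSet([], z)
    labels, n_comp = ndimage.label(hot, structure=np.ones((3, 3), dtype=int))
    patches: list[SourcePatch] = []
    zvals = np.nan_to_num(z.values.astype(float), nan=-np.inf)
    sid = 0
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        area = float(comp_mask.sum()) * z.cell_area_km2
        if area < min_area_km2:
            continue
        rows, cols = np.nonzero(comp_mask)
        zmax = zvals[comp_mask].max()
        at_max = np.nonzero(comp_mask & (zvals == zmax))
        if len(at_max[0]) > 1:  # tie: pick the maximal cell nearest the centroid
            cr, cc = rows.mean(), cols.mean()
            d2 = (at_max[0] - cr) ** 2 + (at_max[1] - cc) ** 2
            k = int(np.argmin(d2))
        else:
            k = 0
        centre_cell = (int(at_max[0][k]), int(at_max[1][k]))
        richness_max = 0
        if richness is not None:
            richness_max = int(richness.values[comp_mask].max())
        sid += 1
        patches.append(
            SourcePatch(
                id=sid,
                polygon=mask_to_polygon(comp_mask, z),
                area_km2=area,
                centre=z.cell_center(*centre_cell),
                centre_cell=centre_cell,
                dominant_service_count=richness_max,
                cells=np.column_stack([rows, cols]),
            )
        )
    return SourceSet(patches, z)
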