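"""Corridor scope from pheromone points: KDE, quantile classes, restoration points.

The pheromone points of a colony run are smoothed into a density surface
with a (GIS-conventional) quartic-kernel KDE, the positive-density cells
are split into nine equal-count quantile classes, and the three highest
classes (7–9) form the *main* corridor — a polygon with explicit width.
The remaining pheromone-bearing cells of the search region are the
*potential* corridor.  Restoration points mark where corridor continuity
breaks: gaps in main-corridor cover along the centreline, resistance
mutation points (local maxima above a high quantile), and crossings of
two corridor centrelines away from the sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .grid import GridRaster
from .mcr import Path


@dataclass
class CorridorRecord:
    id: int
    centreline: Path
    main_polygon: BaseGeometry | None
    potential_polygon: BaseGeometry | None
    main_area_km2: float
    potential_area_km2: float
    main_mask: np.ndarray
    potential_mask: np.ndarray
    region_mask: np.ndarray
    unsupported: bool = False  # no cell reached the top three classes


@dataclass
class CorridorSet:
    corridors: list[CorridorRecord] = field(default_factory=list)
    grid: GridRaster | None = None

    def __len__(self) -> int:
        return len(self.corridors)

    def __iter__(self):
        return iter(self.corridors)

    @property
    def main_area_km2(self) -> float:
        return float(sum(c.main_area_km2 for c in self.corridors))

    @property
    def potential_area_km2(self) -> float:
        return float(sum(c.potential_area_km2 for c in self.corridors))

    def union_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(main, potential) cell masks over all corridors; potential cells
        covered by any corridor's main class are counted as main."""
        if not self.corridors:
            raise ValueError("empty corridor set")
        main = np.zeros_like(self.corridors[0].main_mask)
        potential = np.zeros_like(main)
        for c in self.corridors:
            main |= c.main_mask
            potential |= c.potential_mask
        return main, potential & ~main

    @property
    def main_union_area_km2(self) -> float:
        cell = self.grid.cell_area_km2 if self.grid is not None else 0.0
        return float(self.union_masks()[0].sum()) * cell

    @property
    def potential_union_area_km2(self) -> float:
        cell = self.grid.cell_area_km2 if self.grid is not None else 0.0
        return float(self.union_masks()[1].sum()) * cell


@dataclass
class RestorationPoint:
    location: tuple[float, float]
    cell: tuple[int, int]
    kind: str  # "discontinuity" | "resistance_mutation" | "intersection"
    corridor_ids: tuple[int, ...]


def _quartic_kernel(bandwidth_cells: float) -> np.ndarray:
    r = int(np.ceil(bandwidth_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    u2 = (yy**2 + xx**2) / bandwidth_cells**2
    k = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
    return k / k.sum()


def _gaussian_kernel(bandwidth_cells: float) -> np.ndarray:
    r = int(np.ceil(3 * bandwidth_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(yy**2 + xx**2) / (2 * bandwidth_cells**2))
    return k / k.sum()


def kernel_density(
    points: np.ndarray,
    weights: np.ndarray,
    grid: GridRaster,
    bandwidth_m: float,
    kernel: str = "quartic",
) -> GridRaster:
    """Weighted kernel density of points on the template grid.

    The discrete kernel is normalized to unit mass, so the density raster
    sums to the total point weight up to edge losses; a loss above 1% is
    reported in a warning.  Units: weight per cell.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.size == 0:
        raise ValueError("empty point set")
    if bandwidth_m < grid.cell_size:
        raise ValueError("bandwidth must be at least one cell")
    acc = np.zeros(grid.shape)
    x0, y0 = grid.origin
    cols = np.floor((points[:, 0] - x0) / grid.cell_size).astype(int)
    rows = np.floor((y0 - points[:, 1]) / grid.cell_size).astype(int)
    inb = (rows >= 0) & (rows < grid.shape[0]) & (cols >= 0) & (cols < grid.shape[1])
    np.add.at(acc, (rows[inb], cols[inb]), weights[inb])
    make = _gaussian_kernel if kernel == "gaussian" else _quartic_kernel
    k = make(bandwidth_m / grid.cell_size)
    density = ndimage.convolve(acc, k, mode="constant", cval=0.0)
    total_in = float(weights[inb].sum())
    loss = total_in - float(density.sum())
    if total_in > 0 and loss / total_in > 0.01:
        warnings.warn(
            f"kernel density edge loss {100 * loss / total_in:.1f}% of total mass",
            stacklevel=2,
        )
    return grid.like(density)


def quantile_classes(density: GridRaster, n_classes: int = 9) -> GridRaster:
    """Equal-count classes 1..n over the positive-density cells (n densest).

    Zero-density cells stay 0 (unclassed).  Ties are assigned to the
    higher class, so a constant positive surface collapses entirely into
    the top class (with a warning).
    """
    vals = density.values.astype(float)
    positive = density.valid_mask() & (vals > 0)
    if not positive.any():
        raise ValueError("density surface has no positive cells")
    pv = vals[positive]
    if np.unique(pv).size < n_classes:
        warnings.warn(
            f"fewer than {n_classes} distinct positive density values; "
            "classes collapse",
            stacklevel=2,
        )
    edges = np.quantile(pv, np.arange(1, n_classes) / n_classes)
    classes = np.zeros(density.shape, dtype=np.int16)
    classes[positive] = 1 + np.sum(pv[:, None] >= edges[None, :], axis=1)
    return density.like(classes)


def delineate_corridors(
    classes: GridRaster,
    region: GridRaster | np.ndarray,
    centreline: Path,
    corridor_id: int = 1,
    main_class: int = 7,
) -> CorridorRecord:
    """Main and potential corridor polygons for one corridor.

    Main = cells in the top three classes (class ≥ 7 of 9); potential =
    the remaining pheromone-bearing cells of the search region.  Together
    they partition the pheromone-bearing region exactly.
    """
    from .vectorize import mask_to_polygon

    region_mask = region.values.astype(bool) if isinstance(region, GridRaster) else \
        np.asarray(region, dtype=bool)
    cls = classes.values
    main = region_mask & (cls >= main_class)
    potential = region_mask & (cls >= 1) & ~main
    cell_area = classes.cell_area_km2
    unsupported = not main.any()
    if unsupported:
        warnings.warn(
            f"corridor {corridor_id}: no cell reaches class {main_class}; "
            "flagged unsupported",
            stacklevel=2,
        )
    return CorridorRecord(
        id=corridor_id,
        centreline=centreline,
        main_polygon=mask_to_polygon(main, classes) if main.any() else None,
        potential_polygon=mask_to_polygon(potential, classes) if potential.any() else None,
        main_area_km2=float(main.sum()) * cell_area,
        potential_area_km2=float(potential.sum()) * cell_area,
        main_mask=main,
        potential_mask=potential,
        region_mask=region_mask,
        unsupported=unsupported,
    )


def _runs(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs."""
    out = []
    start = None
    for i, v in enumerate(mask_1d):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask_1d)))
    return out


def restoration_points(
    corridors: CorridorSet,
    resistance: GridRaster,
    gap_min_cells: int = 3,
    mutation_quantile: float = 0.9,
    dedup_radius_m: float | None = None,
    terminal_margin_cells: int = 3,
) -> list[RestorationPoint]:
    """Key points for restoring corridor continuity.

    Emits, in priority order, (i) discontinuities: midpoints of maximal
    runs (≥ ``gap_min_cells``) of centreline cells not covered by the main
    corridor; (ii) resistance mutation points: local maxima of resistance
    along the centreline above the search region's ``mutation_quantile``;
    (iii) intersections of two corridor centrelines away from the source
    terminals.  Points closer than ``dedup_radius_m`` are deduplicated.
    """
    grid = corridors.grid if corridors.grid is not None else resistance
    if dedup_radius_m is None:
        dedup_radius_m = 10 * grid.cell_size
    res = resistance.values.astype(float)
    points: list[RestorationPoint] = []

    for cor in corridors:
        cells = cor.centreline.cells
        if not cells:
            continue
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        # (i) gaps in main-corridor cover along the centreline
        uncovered = ~cor.main_mask[rows, cols]
        for start, stop in _runs(uncovered):
            start = max(start, terminal_margin_cells)
            stop = min(stop, len(cells) - terminal_margin_cells)
            if stop - start >= gap_min_cells:
                mid = cells[(start + stop) // 2]
                points.append(
                    RestorationPoint(grid.cell_center(*mid), mid, "discontinuity",
                                     (cor.id,))
                )
        # (ii) resistance mutation points along the centreline
        prof = res[rows, cols]
        thresh = np.quantile(res[cor.region_mask & resistance.valid_mask()],
                             mutation_quantile)
        for i in range(1, len(cells) - 1):
            if prof[i] >= thresh and prof[i] >= prof[i - 1] and prof[i] >= prof[i + 1] \
                    and (prof[i] > prof[i - 1] or prof[i] > prof[i + 1]):
                points.append(
                    RestorationPoint(grid.cell_center(*cells[i]), cells[i],
                                     "resistance_mutation", (cor.id,))
                )

    # (iii) centreline crossings away from the terminals
    recs = list(corridors)
    for a in range(len(recs)):
        for b in range(a + 1, len(recs)):
            ca, cb = recs[a], recs[b]
            interior_a = set(ca.centreline.cells[terminal_margin_cells:
                                                 len(ca.centreline.cells) - terminal_margin_cells])
            interior_b = set(cb.centreline.cells[terminal_margin_cells:
                                                 len(cb.centreline.cells) - terminal_margin_cells])
            shared = interior_a & interior_b
            if not shared:
                continue
            # cluster shared cells; one point per connected cluster
            mask = np.zeros(grid.shape, dtype=bool)
            for r, c in shared:
                mask[r, c] = True
            labels, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            for comp in range(1, ncomp + 1):
                rr, cc = np.nonzero(labels == comp)
                mid = (int(np.round(rr.mean())), int(np.round(cc.mean())))
                points.append(
                    RestorationPoint(grid.cell_center(*mid), mid, "intersection",
                                     (ca.id, cb.id))
                )

    # deduplicate within dedup_radius_m, earlier (higher-priority) kept
    kept: list[RestorationPoint] = []
    for p in points:
        if all(
            np.hypot(p.location[0] - q.location[0], p.location[1] - q.location[1])
            > dedup_radius_m
            for q in kept
        ):
            kept.append(p)
    return kept
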