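"""Synthetic mountain-karst landscapes for exercising the full pipeline.

The generator emulates the statistical structure the method assumes: a
heterogeneous subtropical mountain landscape with spatially autocorrelated
terrain (smoothed seeded noise), a patchy land-cover mosaic, a karst /
non-karst split with elevated degradation sensitivity inside the karst
region, planted low-resistance channels connecting the ecological source
patches (so corridor recovery has a known ground truth), and the five
local resistance regimes used in behavioural testing.

Everything derives from one integer seed; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .grid import FactorStack, GridRaster
from .sources import SourcePatch, SourceSet
from .vectorize import mask_to_polygon

#: integer land-cover codes used by the generator
LAND_COVER_CODES: dict[int, str] = {
    1: "Forest land",
    2: "Grassland",
    3: "Garden Land",
    4: "Cultivated land",
    5: "Waters",
    6: "Unutilized land",
    7: "Traffic land",
    8: "Construction Land",
}

#: integer bedrock codes
BEDROCK_CODES: dict[int, str] = {
    1: "Non-carbonate rock",
    2: "Limestone",
    3: "Interformation of limestone and dolomite",
    4: "Dolomite",
    5: "Carbonate rock with clastic rock",
}

#: per-class habitat attribute (0-1) used by the service-input generator
HABITAT_ATTRIBUTE: dict[int, float] = {
    1: 1.0, 2: 0.7, 3: 0.6, 4: 0.4, 5: 0.9, 6: 0.2, 7: 0.05, 8: 0.0,
}


@dataclass
class Channel:
    """A planted low-resistance channel between two cells."""

    start: tuple[int, int]
    end: tuple[int, int]
    width_cells: int = 9
    level: str = "low"


@dataclass
class LandscapeSpec:
    shape: tuple[int, int] = (150, 150)
    cell_size: float = 30.0
    seed: int = 0
    n_sources: int = 3
    channels: list[Channel] | None = None  # None: chain consecutive sources
    channel_width_cells: int = 9
    karst_fraction: float = 0.4
    noise_length: float = 8.0  # autocorrelation length, cells
    noise_amplitude: float = 1.0
    crs: str = "EPSG:32648"
    source_radius_cells: int = 4
    min_separation_cells: int = 10

    def __post_init__(self) -> None:
        if self.shape[0] < 20 or self.shape[1] < 20:
            raise ValueError("landscape must be at least 20×20 cells")
        if not 0 <= self.karst_fraction <= 1:
            raise ValueError("karst_fraction must lie in [0, 1]")


@dataclass
class SyntheticLandscape:
    factors: FactorStack  # the six resistance factors
    sensitivity: dict[str, GridRaster]  # rdi, kci, sei in [0, 1]
    sources: SourceSet
    channel_mask: GridRaster
    karst_mask: GridRaster
    spec: LandscapeSpec

    @property
    def grid(self) -> GridRaster:
        return self.factors.reference


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  length: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=length,
                                mode="reflect")
    f -= f.min()
    rng_span = f.max()
    return f / rng_span if rng_span > 0 else np.zeros(shape)


def _quantile_bins(field_: np.ndarray, edges: list[float]) -> np.ndarray:
    """1-based class codes from quantile edges on a continuous field."""
    qs = np.quantile(field_, edges)
    return 1 + np.sum(field_[..., None] >= qs[None, None, :], axis=-1)


def _channel_line_mask(shape: tuple[int, int], channel: Channel) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_line(*channel.start, *channel.end)
    mask[rr, cc] = True
    radius = max((channel.width_cells - 1) // 2, 0)
    if radius:
        dist = ndimage.distance_transform_edt(~mask)
        mask = dist <= radius
    return mask


def make_landscape(spec: LandscapeSpec) -> SyntheticLandscape:
    """Generate aligned factor rasters, sensitivity rasters and sources."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    template = GridRaster(np.zeros(shape), spec.cell_size, (500000.0, 2700000.0),
                          spec.crs)

    # terrain: autocorrelated altitude, slope from an independent rough field
    altitude = 700.0 + 900.0 * _smooth_field(rng, shape, spec.noise_length)
    slope = 45.0 * _smooth_field(rng, shape, spec.noise_length / 2)
    vegetation = 100.0 * _smooth_field(rng, shape, spec.noise_length)
    soil = 45.0 * _smooth_field(rng, shape, spec.noise_length)

    # karst / non-karst split with bedrock classes inside the karst region
    karst_field = _smooth_field(rng, shape, spec.noise_length * 1.5)
    if spec.karst_fraction <= 0:
        karst = np.zeros(shape, dtype=bool)
    elif spec.karst_fraction >= 1:
        karst = np.ones(shape, dtype=bool)
    else:
        karst = karst_field >= np.quantile(karst_field, 1 - spec.karst_fraction)
    bedrock = np.ones(shape, dtype=np.int16)  # non-carbonate background
    rock_field = _smooth_field(rng, shape, spec.noise_length / 2)
    if karst.any():
        sub = _quantile_bins(rock_field, [0.25, 0.5, 0.75])  # 1..4
        bedrock[karst] = (sub + 1)[karst]  # codes 2..5

    # patchy land-cover mosaic from quantile bins of a smooth field
    lc_field = _smooth_field(rng, shape, spec.noise_length / 1.5)
    lc_edges = [0.40, 0.55, 0.62, 0.85, 0.90, 0.95, 0.97]
    land_cover = _quantile_bins(lc_field, lc_edges).astype(np.int16)

    # sensitivity indices: low background, elevated inside the karst region
    def sens(scale_len: float) -> np.ndarray:
        base = 0.05 + 0.10 * _smooth_field(rng, shape, scale_len)
        extra = 0.35 + 0.45 * _smooth_field(rng, shape, scale_len)
        return np.clip(np.where(karst, base + extra, base), 0.0, 1.0)

    rdi = sens(spec.noise_length)
    kci = sens(spec.noise_length * 1.2)
    sei = sens(spec.noise_length * 0.8)

    # source placement: greedy on low-resistance terrain with minimum
    # pairwise separation
    margin = spec.source_radius_cells + 2
    suitability = (
        (land_cover == 1).astype(float) + (slope < 15) + (altitude < 1300)
    ) - karst.astype(float)
    noise_tiebreak = rng.random(shape) * 0.01
    order = np.argsort(-(suitability + noise_tiebreak), axis=None, kind="stable")
    centres: list[tuple[int, int]] = []
    for flat in order:
        r, c = divmod(int(flat), shape[1])
        if not (margin <= r < shape[0] - margin and margin <= c < shape[1] - margin):
            continue
        if all(max(abs(r - rr), abs(c - cc)) >= spec.min_separation_cells
               for rr, cc in centres):
            centres.append((r, c))
        if len(centres) == spec.n_sources:
            break
    if len(centres) < spec.n_sources:
        raise ValueError(
            f"could only place {len(centres)} of {spec.n_sources} disjoint "
            "sources; shrink n_sources or the separation"
        )

    # planted channels: default chains consecutive sources
    channels = spec.channels
    if channels is None:
        channels = [
            Channel(centres[i], centres[i + 1], spec.channel_width_cells)
            for i in range(len(centres) - 1)
        ]
    channel_mask = np.zeros(shape, dtype=bool)
    for ch in channels:
        channel_mask |= _channel_line_mask(shape, ch)

    # source patches: disks around the centres
    source_mask = np.zeros(shape, dtype=bool)
    patches: list[SourcePatch] = []
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (r, c) in enumerate(centres, start=1):
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= spec.source_radius_cells**2
        source_mask |= disk
        cells = np.column_stack(np.nonzero(disk))
        patches.append(
            SourcePatch(
                id=i,
                polygon=mask_to_polygon(disk, template),
                area_km2=float(disk.sum()) * template.cell_area_km2,
                centre=template.cell_center(r, c),
                centre_cell=(r, c),
                cells=cells,
            )
        )

    # plant low-resistance conditions along channels and inside sources
    low = channel_mask | source_mask
    land_cover[low] = 1  # forest
    slope[low] = 5.0
    altitude[low] = np.minimum(altitude[low], 750.0)
    vegetation[low] = np.minimum(vegetation[low], 20.0)
    soil[low] = 5.0
    bedrock[low] = 1
    for s in (rdi, kci, sei):
        s[low] = 0.05

    factors = FactorStack(
        {
            "land_cover": template.like(land_cover),
            "slope": template.like(slope),
            "altitude": template.like(altitude),
            "vegetation_coverage": template.like(vegetation),
            "soil_thickness": template.like(soil),
            "bedrock": template.like(bedrock),
        }
    )
    return SyntheticLandscape(
        factors=factors,
        sensitivity={
            "rdi": template.like(rdi),
            "kci": template.like(kci),
            "sei": template.like(sei),
        },
        sources=SourceSet(patches, template),
        channel_mask=template.like(channel_mask.astype(np.uint8)),
        karst_mask=template.like(karst.astype(np.uint8)),
        spec=spec,
    )


def make_service_stack(spec: LandscapeSpec,
                       landscape: SyntheticLandscape | None = None) -> dict:
    """Physically plausible inputs for the five service operators.

    Returns a dict of aligned rasters (APAR, epsilon, habitat, degradation,
    RUSLE factors, water-balance terms, NDVI) plus the cropland mask,
    region mask and per-region grain output used by food allocation.
    """
    if landscape is None:
        landscape = make_landscape(spec)
    rng = np.random.default_rng(spec.seed + 1)
    shape = spec.shape
    template = landscape.grid

    def f(length_scale: float = spec.noise_length) -> np.ndarray:
        return _smooth_field(rng, shape, length_scale)

    land_cover = landscape.factors["land_cover"].values
    habitat = np.vectorize(HABITAT_ATTRIBUTE.get)(land_cover).astype(float)
    built = (land_cover == 7) | (land_cover == 8)
    built_influence = ndimage.gaussian_filter(built.astype(float), sigma=4)
    built_influence /= built_influence.max() if built_influence.max() > 0 else 1.0
    degradation = np.clip(0.4 * f() + 0.6 * built_influence, 0.0, 1.0)

    out = {
        "apar": template.like(1000.0 + 2000.0 * f()),
        "epsilon": template.like(0.3 + 1.2 * f()),
        "habitat": template.like(habitat),
        "degradation": template.like(degradation),
        "erodibility": template.like(0.1 + 0.4 * f()),
        "erosivity": template.like(100.0 + 500.0 * f()),
        "ls": template.like(0.5 + 9.5 * f()),
        "cover": template.like(f()),
        "practice": template.like(f()),
        "precipitation": template.like(900.0 + 700.0 * f()),
        "evapotranspiration": template.like(400.0 + 400.0 * f()),
        "runoff": template.like(50.0 + 250.0 * f()),
        "ndvi": template.like(0.1 + 0.8 * f()),
    }
    # source patches are, by construction, the service-richest spots: the
    # generator plants high productivity, intact habitat and strong
    # regulation there so hot-spot extraction has a recoverable target
    source_mask = np.zeros(shape, dtype=bool)
    for p in landscape.sources:
        source_mask[p.cells[:, 0], p.cells[:, 1]] = True
    out["apar"].values[source_mask] = 2900.0
    out["epsilon"].values[source_mask] = 1.45
    out["degradation"].values[source_mask] *= 0.05
    out["erodibility"].values[source_mask] = 0.48
    out["erosivity"].values[source_mask] = 580.0
    out["ls"].values[source_mask] = 9.5
    out["cover"].values[source_mask] = 0.1
    out["practice"].values[source_mask] = 0.1
    out["precipitation"].values[source_mask] = 1580.0
    out["evapotranspiration"].values[source_mask] = 420.0
    out["runoff"].values[source_mask] = 60.0

    cropland = land_cover == 4
    region = np.ones(shape, dtype=np.int16)
    region[:, shape[1] // 2 :] = 2
    out["cropland_mask"] = template.like(cropland.astype(np.uint8))
    out["region_mask"] = template.like(region)
    # grain output proportional to each region's cropland area (t of grain
    # energy, arbitrary consistent units)
    out["region_output"] = {
        1: float((cropland & (region == 1)).sum()) * 0.5,
        2: float((cropland & (region == 2)).sum()) * 0.5,
    }
    return out


@dataclass
class RegimeScenario:
    """One of the five local resistance regimes with terminals and geometry."""

    resistance: GridRaster
    start: tuple[int, int]
    end: tuple[int, int]
    info: dict


def make_regime_scenario(
    kind: str,
    shape: tuple[int, int] = (60, 100),
    seed: int = 0,
    cell_size: float = 30.0,
    low: float = 5.0,
    high: float = 80.0,
) -> RegimeScenario:
    """Local resistance regimes for behavioural tests of the ant colony.

    (a) uniformly high resistance along the corridor; (b) uniformly low;
    (c) a high band across the corridor pierced by one low gap; (d) a
    uniform low field abutting a high block; (e) a fragmented mosaic of
    high patches separated by a low seam.
    """
    if kind not in {"a", "b", "c", "d", "e"}:
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    noise = 0.05 * rng.standard_normal(shape)
    mid = nrows // 2
    start = (mid, 3)
    end = (mid, ncols - 4)
    info: dict = {"kind": kind, "low": low, "high": high}

    if kind == "a":
        res = high * (1.0 + noise)
    elif kind == "b":
        res = low * (1.0 + noise)
    elif kind == "c":
        res = low * (1.0 + noise)
        c0, c1 = ncols // 2 - 4, ncols // 2 + 4
        g0 = max(nrows // 4 - 2, 1)
        g1 = g0 + 5
        res[:, c0:c1] = high * (1.0 + noise[:, c0:c1])
        res[g0:g1, c0:c1] = low * (1.0 + noise[g0:g1, c0:c1])
        info.update(band_cols=(c0, c1), gap_rows=(g0, g1))
    elif kind == "d":
        res = low * (1.0 + noise)
        b0 = mid + 3
        c0, c1 = ncols // 3, 2 * ncols // 3
        res[b0:, c0:c1] = high * (1.0 + noise[b0:, c0:c1])
        info.update(block_rows=(b0, nrows), block_cols=(c0, c1))
    else:  # e: two high patches with a low seam between them
        res = low * (1.0 + noise)
        c0, c1 = ncols // 2 - 6, ncols // 2 + 6
        s0, s1 = mid - 2, mid + 2
        res[:s0, c0:c1] = high * (1.0 + noise[:s0, c0:c1])
        res[s1:, c0:c1] = high * (1.0 + noise[s1:, c0:c1])
        info.update(band_cols=(c0, c1), seam_rows=(s0, s1))

    res = np.clip(res, low * 0.5, None)
    raster = GridRaster(res, cell_size, (500000.0, 2700000.0), "EPSG:32648")
    return RegimeScenario(raster, start, end, info)
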