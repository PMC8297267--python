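"""End-to-end ecological-security-pattern pipeline.

Chains the stages — synthetic landscape, ecosystem services, hot-spot
source extraction, entropy-weighted and sensitivity-corrected resistance,
least-cost corridor skeletons, per-corridor ant colonies, KDE corridor
delineation and restoration points — from a single configuration, and
optionally writes every artifact (rasters, polygons, points, log) to a
directory.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import numpy as np

from . import services as svc
from .aco import AntParams, PheromoneField, filter_pheromone_points, run_colony, search_region
from .corridor import (
    CorridorRecord,
    CorridorSet,
    RestorationPoint,
    delineate_corridors,
    kernel_density,
    quantile_classes,
    restoration_points,
)
from .grid import GridRaster
from .io import write_raster, write_vector
from .mcr import Path, corridor_network
from .resistance import (
    ClassificationTable,
    ResistanceSurface,
    base_resistance,
    classify_stack,
    correct_resistance,
    entropy_weights,
    sensitivity_index,
)
from .sources import (
    SourceSet,
    extract_source_patches,
    gi_star,
    service_richness,
    top_quantile_mask,
)
from .synth import (
    BEDROCK_CODES,
    LAND_COVER_CODES,
    LandscapeSpec,
    SyntheticLandscape,
    make_landscape,
    make_service_stack,
)


@dataclass
class PipelineConfig:
    landscape: LandscapeSpec = field(default_factory=LandscapeSpec)
    ant: AntParams = field(default_factory=AntParams)
    service_quantile: float = 0.20
    gi_radius_cells: float = 3.0
    z_threshold: float = 1.65
    #: minimum source area; None scales to 25 cells of the landscape grid
    #: (the fixed-area filter of county-scale studies is far larger than a
    #: desk-scale synthetic landscape)
    min_area_km2: float | None = None
    recompute_weights: bool = False
    kde_bandwidth_cells: float = 10.0
    n_classes: int = 9
    main_class: int = 7
    gap_min_cells: int = 3
    mutation_quantile: float = 0.9
    k_neighbors: int = 2


@dataclass
class CorridorRun:
    skeleton: Path
    field: PheromoneField
    density: GridRaster
    classes: GridRaster
    record: CorridorRecord


@dataclass
class PipelineResult:
    landscape: SyntheticLandscape
    service_rasters: dict[str, GridRaster]
    richness: GridRaster
    z_scores: GridRaster
    sources: SourceSet
    resistance: ResistanceSurface
    factor_weights: dict[str, float]
    corridor_runs: list[CorridorRun]
    corridors: CorridorSet
    restoration: list[RestorationPoint]
    elapsed_s: float
    log: dict


def compute_services(inputs: dict) -> dict[str, GridRaster]:
    """The five service rasters from a generated (or loaded) input dict."""
    return {
        "gas_regulation": svc.compute_npp(inputs["apar"], inputs["epsilon"]),
        "habitat_maintenance": svc.compute_habitat_quality(
            inputs["habitat"], inputs["degradation"]
        ),
        "soil_conservation": svc.compute_soil_conservation(
            inputs["erodibility"], inputs["erosivity"], inputs["ls"],
            inputs["cover"], inputs["practice"],
        ),
        "water_supply": svc.compute_water_yield(
            inputs["precipitation"], inputs["evapotranspiration"], inputs["runoff"]
        ),
        "food_supply": svc.allocate_food_supply(
            inputs["ndvi"], inputs["cropland_mask"], inputs["region_mask"],
            inputs["region_output"],
        ),
    }


def build_resistance(
    landscape: SyntheticLandscape,
    table: ClassificationTable | None = None,
    recompute_weights: bool = False,
) -> tuple[ResistanceSurface, dict[str, float]]:
    """Classified + weighted basic resistance, sensitivity-corrected."""
    table = table or ClassificationTable()
    categories = {"land_cover": LAND_COVER_CODES, "bedrock": BEDROCK_CODES}
    classified = classify_stack(landscape.factors, table, categories)
    weights = dict(table.weights)
    if recompute_weights:
        names = classified.names
        mat = np.column_stack(
            [classified[n].values.ravel().astype(float) for n in names]
        )
        w = entropy_weights(mat)
        weights = dict(zip(names, w.tolist()))
    basic = base_resistance(classified, weights)
    sens = landscape.sensitivity
    stack = sensitivity_index(sens["rdi"], sens["kci"], sens["sei"])
    return correct_resistance(basic, stack), weights


def extract_sources(
    service_rasters: dict[str, GridRaster],
    config: PipelineConfig,
) -> tuple[GridRaster, GridRaster, SourceSet]:
    """Top-quantile masks -> richness -> Gi* -> filtered source patches."""
    masks = [top_quantile_mask(r, config.service_quantile)
             for r in service_rasters.values()]
    richness = service_richness(masks)
    grid = richness
    z = gi_star(richness, config.gi_radius_cells * grid.cell_size)
    min_area = config.min_area_km2
    if min_area is None:
        min_area = 25 * grid.cell_area_km2
    srcs = extract_source_patches(z, config.z_threshold, min_area, richness)
    return richness, z, srcs


def run_corridor(
    resistance: GridRaster,
    skeleton: Path,
    start: tuple[int, int],
    end: tuple[int, int],
    config: PipelineConfig,
    seed: int,
    corridor_id: int = 1,
) -> CorridorRun:
    """One corridor: buffer, colony, KDE, quantile classes, delineation."""
    region = search_region(skeleton, resistance, config.ant.buffer_m)
    params = AntParams(**{**asdict(config.ant), "seed": seed})
    fieldp = run_colony(resistance, region, start, end, params)
    points, weights = filter_pheromone_points(fieldp)
    density = kernel_density(
        points, weights, resistance,
        config.kde_bandwidth_cells * resistance.cell_size,
    )
    classes = quantile_classes(density, config.n_classes)
    record = delineate_corridors(
        classes, region, skeleton, corridor_id, config.main_class
    )
    return CorridorRun(skeleton, fieldp, density, classes, record)


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | FsPath | None = None,
) -> PipelineResult:
    """Run every stage on the synthetic landscape of the configuration."""
    t0 = time.time()
    config = config or PipelineConfig()
    spec = config.landscape

    landscape = make_landscape(spec)
    inputs = make_service_stack(spec, landscape)
    service_rasters = compute_services(inputs)
    richness, z, hotspot_sources = extract_sources(service_rasters, config)

    sources = hotspot_sources
    if len(sources) < 2:
        warnings.warn(
            "hot-spot analysis found fewer than two sources; falling back "
            "to the generator's planted source patches",
            stacklevel=2,
        )
        sources = landscape.sources

    surface, weights = build_resistance(
        landscape, recompute_weights=config.recompute_weights
    )
    # the min-max standardized sensitivity is exactly 0 at its minimum
    # cell, which would make that cell free to cross; floor the corrected
    # surface at 0.1% of the mean basic resistance for traversal
    floor = 1e-3 * float(np.nanmean(surface.basic.values))
    traversal = surface.corrected.like(
        np.maximum(surface.corrected.values, floor)
    )
    skeletons = corridor_network(
        traversal, sources, k_neighbors=config.k_neighbors
    )

    runs: list[CorridorRun] = []
    terminals = {p.id: p.centre_cell for p in sources}
    for i, skel in enumerate(skeletons, start=1):
        a, b = skel.endpoints
        run = run_corridor(
            traversal, skel, terminals[a], terminals[b], config,
            seed=config.ant.seed + i, corridor_id=i,
        )
        runs.append(run)

    corridors = CorridorSet([r.record for r in runs], surface.corrected)
    resto = restoration_points(
        corridors, surface.corrected, config.gap_min_cells,
        config.mutation_quantile,
    )
    elapsed = time.time() - t0
    log = {
        "config": {
            "landscape": asdict(spec) if spec.channels is None else
            {**asdict(spec), "channels": [asdict(c) for c in spec.channels]},
            "ant": asdict(config.ant),
            "service_quantile": config.service_quantile,
            "z_threshold": config.z_threshold,
            "kde_bandwidth_cells": config.kde_bandwidth_cells,
        },
        "factor_weights": weights,
        "n_sources": len(sources),
        "total_source_area_km2": sources.total_area_km2,
        "mean_basic_resistance": float(np.nanmean(surface.basic.values)),
        "mean_corrected_resistance": float(np.nanmean(surface.corrected.values)),
        "n_corridors": len(runs),
        "main_corridor_area_km2": corridors.main_union_area_km2,
        "potential_corridor_area_km2": corridors.potential_union_area_km2,
        "n_restoration_points": len(resto),
        "elapsed_s": elapsed,
    }
    result = PipelineResult(
        landscape=landscape,
        service_rasters=service_rasters,
        richness=richness,
        z_scores=z,
        sources=sources,
        resistance=surface,
        factor_weights=weights,
        corridor_runs=runs,
        corridors=corridors,
        restoration=resto,
        elapsed_s=elapsed,
        log=log,
    )
    if outdir is not None:
        write_artifacts(result, FsPath(outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: FsPath) -> None:
    """Write every declared artifact of a pipeline run."""
    outdir.mkdir(parents=True, exist_ok=True)
    crs = result.richness.crs
    for name, raster in result.service_rasters.items():
        write_raster(raster, outdir / f"service_{name}.tif")
    write_raster(result.richness, outdir / "service_richness.tif")
    write_raster(result.z_scores, outdir / "hotspot_z.tif")
    write_raster(result.resistance.basic, outdir / "resistance_basic.tif")
    write_raster(result.resistance.corrected, outdir / "resistance_corrected.tif")
    write_vector(result.sources.to_features(), outdir / "sources.geojson", crs=crs)

    from shapely.geometry import LineString, Point

    lines = []
    mains = []
    potentials = []
    for run in result.corridor_runs:
        write_raster(run.field.tau, outdir / f"corridor_{run.record.id:02d}_tau.tif")
        write_raster(run.density, outdir / f"corridor_{run.record.id:02d}_density.tif")
        write_raster(run.classes, outdir / f"corridor_{run.record.id:02d}_classes.tif")
        grid = run.density
        lines.append(
            {
                "geometry": LineString(run.skeleton.xy(grid)),
                "properties": {
                    "id": run.record.id,
                    "total_cost": run.skeleton.total_cost,
                    "endpoints": list(run.skeleton.endpoints),
                },
            }
        )
        if run.record.main_polygon is not None:
            mains.append(
                {
                    "geometry": run.record.main_polygon,
                    "properties": {"id": run.record.id,
                                   "area_km2": run.record.main_area_km2},
                }
            )
        if run.record.potential_polygon is not None:
            potentials.append(
                {
                    "geometry": run.record.potential_polygon,
                    "properties": {"id": run.record.id,
                                   "area_km2": run.record.potential_area_km2},
                }
            )
    write_vector(lines, outdir / "corridor_centrelines.geojson", crs=crs)
    write_vector(mains, outdir / "corridors_main.geojson", crs=crs)
    write_vector(potentials, outdir / "corridors_potential.geojson", crs=crs)
    write_vector(
        [
            {
                "geometry": Point(p.location),
                "properties": {"kind": p.kind, "corridors": list(p.corridor_ids)},
            }
            for p in result.restoration
        ],
        outdir / "restoration_points.geojson",
        crs=crs,
    )
    (outdir / "pipeline_log.json").write_text(json.dumps(result.log, indent=1))
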