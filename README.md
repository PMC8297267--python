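# ecocorridor

Construction of **ecological security patterns** on raster landscapes:
ecological sources, corridors with an explicit spatial width, and
restoration points, for landscape ecologists and conservation planners
working on fragmented (in particular karst) mountain landscapes.

Corridor extraction by minimum cumulative resistance (MCR) gives a line,
not a belt; circuit theory gives a belt only by subjective thresholding.
`ecocorridor` implements a pipeline that derives corridor *width* from the
collective behaviour of a modified ant colony:

1. **Sources** — five ecosystem services (gas regulation NPP = APAR·ε,
   habitat maintenance Q = H·(1 − D^z/(D^z + k^z)), soil conservation
   A = K·R·LS·(1 − C·P), water supply W = P − ET − Q, NDVI-proportional
   food supply) are scored per cell; the top 20% of each service is
   merged into a richness surface; Getis-Ord Gi* hot-spot analysis plus a
   minimum-area filter yields the ecological source patches.
2. **Resistance** — six classified factors (land cover, slope, altitude,
   vegetation coverage, soil thickness, bedrock) are combined with
   entropy-method weights into a basic resistance surface R, corrected by
   the ecological sensitivity index,
   R_i = R · ESI_std / mean(ESI_std), ESI = a·RDI + b·KCI + c·SEI.
3. **Corridors** — least-cost skeletons between source terminals
   (MCR = min Σ D_ij·R_i, Dijkstra on the cell graph); then, inside a
   1500 m buffer of each skeleton, 200 ants × 50 iterations walk between
   the terminals with transition rule p ∝ τ^α(1/R)^β under a ≤ 90°
   direction constraint, skipping and jumping over high-resistance cells.
   Above-average pheromone cells become weighted points; a quartic-kernel
   KDE and nine quantile grades turn them into the **main** corridor
   (grades 7–9) and the **potential** corridor (the rest of the searched
   area).
4. **Restoration points** — gaps in main-corridor cover along a
   centreline, resistance mutation points, and corridor crossings.

A seeded synthetic-landscape generator (autocorrelated terrain, patchy
land cover, karst/non-karst split, planted low-resistance channels with
known ground truth) makes every stage testable without any data download.

## Worked example

```python
import ecocorridor as ec

result = ec.run_pipeline(ec.PipelineConfig(), outdir="out")
for k in ("n_sources", "total_source_area_km2", "mean_basic_resistance",
          "mean_corrected_resistance", "n_corridors",
          "main_corridor_area_km2", "potential_corridor_area_km2",
          "n_restoration_points"):
    v = result.log[k]
    print(f"{k}: {round(v, 2) if isinstance(v, float) else v}")
```

prints, for the default 150×150-cell (30 m) synthetic landscape:

```
n_sources: 21
total_source_area_km2: 6.46
mean_basic_resistance: 37.48
mean_corrected_resistance: 43.58
n_corridors: 34
main_corridor_area_km2: 7.62
potential_corridor_area_km2: 7.66
n_restoration_points: 16
```

21 hot-spot patches pass the area filter and become sources; the mean
cell resistance rises from 37.5 to 43.6 after the sensitivity correction
(the karst region is penalized); 34 least-cost corridors connect the
sources, and the ant colonies delineate 7.6 km² of main corridor
surrounded by 7.7 km² of potential corridor, with 16 points where
corridor continuity breaks. `out/` receives every artifact: the five
service GeoTIFFs, richness and z-score rasters, both resistance surfaces,
per-corridor pheromone/density/class rasters, and GeoJSON sources,
centrelines, corridor polygons and restoration points, plus a JSON log of
every parameter.

The same stages are available individually (`ec.make_landscape`,
`ec.gi_star`, `ec.cost_distance`, `ec.run_colony`, `ec.kernel_density`,
…) and as CLI subcommands:

```sh
ecocorridor pipeline --seed 7 --out out/
ecocorridor synth --seed 7 --out land/
ecocorridor resistance --out res/
ecocorridor aco res/resistance_corrected.tif --start 20 20 --end 120 120 --out aco/
```

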