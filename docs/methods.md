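# Methods

`ecocorridor` builds ecological security patterns — sources, corridors
with explicit width, and restoration points — on raster landscapes. This
note documents the models implemented, the parameters that matter, the
synthetic data the test-bed generates, and the design choices made where
the procedure left them open.

## Pipeline overview

1. **Ecosystem services.** Five per-cell service surfaces: gas regulation
   (NPP = APAR·ε), habitat maintenance (InVEST-style habitat quality
   Q = H·(1 − D^z/(D^z + k^z)), defaults z = 2, k = 0.5), soil
   conservation (RUSLE overlay A = K·R·LS·(1 − C·P)), water supply (annual
   balance W = P − ET − Q, mm) and food supply (regional grain output
   spread over cropland in proportion to NDVI, mass-conserving per
   region). Negative water balances are retained and warned about, not
   clipped, so input problems stay visible.
2. **Sources.** The top 20% of each service raster is marked, a per-cell
   service-richness count (0–5) merges the five masks, Getis-Ord Gi* with
   binary distance-band weights (self included) scores local clustering,
   and 8-connected clusters with z ≥ 1.65 (90% confidence; configurable)
   above a minimum area become ecological sources. Each source's centre —
   the maximal-z cell, ties broken toward the centroid — is a corridor
   terminal.
3. **Resistance.** Six factors (land cover, slope, altitude, vegetation
   coverage, soil thickness, bedrock type) are classified to basic
   resistance coefficients (5–100) and combined as a weighted sum. The
   shipped default weights are entropy-weight values for a reference
   karst county; `entropy_weights` re-derives them from the data on
   request (column-normalize to proportions, e = −(ln n)⁻¹ Σ p ln p,
   w ∝ 1 − e). An ecological sensitivity index
   ESI = 0.483·RDI + 0.282·KCI + 0.235·SEI (rocky desertification, karst
   collapse, soil erosion, each rescaled to [0, 1]) is min-max
   standardized and each cell's basic resistance is scaled by the ratio
   of its standardized sensitivity to the regional mean, so that cells of
   average sensitivity keep their basic resistance and the regional mean
   resistance is approximately preserved.
4. **Corridor skeletons (MCR).** Minimum cumulative resistance
   MCR = min Σ D_ij·R_i over 8-connected paths, step cost = distance ×
   endpoint-average resistance, solved by Dijkstra on the sparse cell
   graph. Terminal pairs come from the union of the cost-weighted minimum
   spanning tree and each terminal's k = 2 nearest-by-cost neighbours —
   this reproduces ring topologies on symmetric inputs; near-duplicate
   paths (≥ 90% shared cells) are merged.
5. **Ant colony.** Per corridor, 200 ants per iteration for 50 iterations
   walk from start to end inside a 1500 m buffer of the skeleton. Moves
   follow the Ant System kernel p ∝ τ^α (1/R)^β (α = 1, β = 2), restricted
   to unvisited in-region neighbours within 90° of (a) the ant's previous
   step and (b) a directional layer. When every admissible neighbour lies
   above the high-resistance quantile (default 0.9), the ant jumps
   uniformly to a nearby region cell (Chebyshev radius 3) and its
   direction memory resets. After each iteration τ evaporates by ρ = 0.1
   and each successful ant deposits Q/L (Q = 1, L = its accumulated cost)
   on the passable cells it visited; cells above the high-resistance
   threshold are "skipped" and receive no deposit, which is what later
   exposes barriers as corridor discontinuities. Fixed seeds give
   bit-identical fields.
6. **Corridor scope.** Visited cells with above-average pheromone become
   weighted points; a quartic-kernel KDE (bandwidth 10 cells) smooths
   them into a density surface; the positive-density cells are split into
   nine equal-count quantile classes; classes 7–9 are the **main**
   corridor, the remaining pheromone-bearing region the **potential**
   corridor (together they partition the pheromone-bearing region
   exactly). Restoration points are (i) midpoints of ≥ 3-cell runs of
   centreline not covered by the main corridor, (ii) local maxima of
   resistance along the centreline above the region's 0.9 quantile, and
   (iii) crossings of two centrelines away from the terminals, in that
   priority, deduplicated within ten cell widths.

## The directional layer

The corridor search is a two-terminal problem on grids of 10⁴–10⁵ cells.
A transition kernel with only the previous-step angle constraint is an
isotropic persistent random walk: in experiments at 100×100 only 2–5% of
ants reached the far terminal and the pheromone field stayed diffuse. The
directional layer fixes this: a least-cost accumulation is seeded at the
*destination*, and each cell's backlink direction (one step along the
cheapest route to the destination) becomes a per-cell reference
direction; admissible moves must have a nonnegative inner product with
it. Ants can move laterally (90° tolerance on both constraints) — which
is what samples the corridor's width — but cannot walk systematically
away from the goal. With the layer, essentially all ants complete, and
the field reproduces the expected local behaviours: mass concentrates on
low-resistance ground, funnels through gaps in barriers, and collects in
low seams between high patches.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| n_ants / n_iterations | 200 / 50 | — | colony size and generations |
| buffer_m | 1500 | m | half-width of the search region |
| α, β | 1, 2 | — | pheromone / heuristic exponents |
| ρ, Q, τ₀ | 0.1, 1, 0.1 | — | evaporation, deposit quantum, initial floor |
| jump_threshold | 0.9 | quantile | resistance above which a cell is "high" |
| jump_radius | 3 | cells | Chebyshev radius of the jump set |
| z-threshold (Gi*) | 1.65 | z | hot-spot significance (90%) |
| min source area | 6.26 | km² | patch filter at county scale; the pipeline default scales to 25 cells on desk-scale grids |
| KDE bandwidth | 10 | cells | quartic kernel radius |
| classes / main | 9 / ≥ 7 | — | quantile grades; top three are "main" |
| ESI weights (a, b, c) | 0.483 / 0.282 / 0.235 | — | RDI / KCI / SEI weights |

Colony size, iteration count and buffer width are the study conditions
the package reproduces; the kernel constants are conventional Ant System
values and all are configurable.

## Synthetic landscapes

`make_landscape` generates what the method assumes about real mountain
karst landscapes: spatially autocorrelated terrain (Gaussian-filtered
seeded white noise, autocorrelation length 8 cells), a patchy land-cover
mosaic dominated by forest and cropland, a karst region (default 40% of
the area) carrying carbonate bedrock classes and elevated
rocky-desertification / karst-collapse / soil-erosion indices, source
patches (disks, radius 4 cells) placed greedily on favourable terrain
with ≥ 10 cells separation, and planted low-resistance channels (default
width 9 cells ≈ 270 m at the 30 m default cell, i.e. a realistic corridor
width) connecting consecutive sources. Service inputs are boosted inside
the source disks so hot-spot extraction has a recoverable target. The
default pipeline landscape is 150×150 cells at 30 m; the corridor-recovery
test-bed is 200×200. These sizes keep a full run under a minute on one
CPU while leaving every stage non-trivial.

What the generator does **not** emulate: real geomorphology and
hydrology (drainage networks, aspect-dependent vegetation), anisotropic
human disturbance (roads as linear barriers), registration error between
layers, or the areal extent of a county (10³–10⁴ km²). Passing tests
therefore demonstrate the internal correctness and the qualitative
behaviours of the method, not calibrated agreement with any real
landscape.

## Numerical choices and degenerate inputs

- Classification intervals are left-closed, right-open ([15, 25) → 30),
  top class closed; printed tables with touching endpoints need such a
  convention.
- Quantile ties go to the *higher* class; a constant positive density
  collapses into class 9 with a warning.
- A spatially constant ESI makes the correction a documented no-op
  (corrected = basic) rather than 0/0.
- Min-max standardization zeroes the least-sensitive cell, so the
  pipeline floors the corrected surface at 0.1% of the mean basic
  resistance before cost-distance — resistance must be strictly positive
  for traversal.
- Cost-distance treats nodata cells as untraversable; unreachable cells
  get infinite cost and are counted.
- The KDE kernel is normalized to unit discrete mass, so density sums to
  total point weight; edge losses above 1% are warned about.
- Pheromone comparisons in the behavioural tests use deposited mass —
  τ net of the decayed initialization floor τ₀(1−ρ)^T — because the floor
  is initialization, not information left by ants.

## Known limitations

- The corridor-width recovery against a planted 9-cell channel scores an
  intersection-over-union of roughly 0.45–0.7 across seeds (≈ 0.55 on
  average): the KDE bandwidth (10 cells) smears the main corridor 1–3
  cells past the channel edge while the winner-take-all pheromone
  dynamics under-fill the channel margins. The delineated corridor is
  systematically in the right place but its width estimate carries
  ± 2–3 cells of uncertainty at these settings.
- Gi* z-scores assume enough valid cells for the normal approximation;
  on very small grids the brute-force formula is exact but the 1.65
  cut-off is nominal.
- The MST ∪ k-nearest pairing rule is one defensible corridor topology;
  real studies may prescribe their own pairing.
- Reprojection between CRSs is out of scope; all layers must share a
  projected CRS before alignment.
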