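"""Improved ant-colony corridor search on a resistance raster.

Stochastic ants walk from a source terminal toward a target terminal
inside a buffered search region around the least-cost corridor skeleton.
The pheromone they accumulate encodes not just the optimal line but the
*width* of the corridor: cells many cheap paths share collect more
pheromone.

The colony follows the classic Ant System transition kernel — a move to
neighbour j is chosen with probability proportional to τ_j^α · (1/R_j)^β —
with three modifications for cost rasters:

* direction memory: the angle between the previous and the next step is
  at most 90°, which stops ants from milling in local optima;
* a directional layer: the next step must also lie within 90° of the
  cost-distance flow direction toward the destination (the backlink
  direction of a least-cost accumulation seeded at the target), so ants
  may spread laterally across the corridor but never walk away from the
  goal — this is what keeps the walk from degenerating into an
  unguided random walk on large grids;
* no revisiting: an ant never re-enters a cell it already visited;
* jumping: when every admissible neighbour lies above a high-resistance
  quantile, the ant leaps to a random region cell within a small Chebyshev
  radius (and its direction memory resets), letting it skip barriers.

Pheromone is updated globally once per iteration: evaporation
τ ← (1 − ρ)·τ, then every ant that reached the target deposits Q/L over
the cells it visited, L being its accumulated step cost.  Skipped cells —
those above the high-resistance threshold, which an ant can only enter by
jumping — receive no deposit: pheromone marks the passable ground, so a
barrier crossed by jumps stays pheromone-free and later shows up as a
corridor discontinuity.  The run is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridRaster
from .mcr import Path

# 8-neighbour offsets and step lengths (unit cells)
_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)
_STEP_LEN = np.sqrt((_OFFSETS**2).sum(axis=1).astype(float))
# allowed[prev_dir, next_dir]: inner product of unit step vectors >= 0;
# row 8 = no direction memory (all moves allowed)
_UNIT = _OFFSETS / _STEP_LEN[:, None]
_ALLOWED = np.vstack([(_UNIT @ _UNIT.T) >= -1e-12, np.ones(8, dtype=bool)])


@dataclass
class AntParams:
    """Colony parameters.

    Defaults follow the study conditions: 200 ants per iteration, 50
    iterations, and a 1500 m search buffer; the kernel exponents and
    evaporation (α=1, β=2, ρ=0.1, Q=1) are conventional Ant System values.
    """

    n_ants: int = 200
    n_iterations: int = 50
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.1
    deposit: float = 1.0
    jump_radius: int = 3
    jump_threshold: float = 0.9
    max_steps: int | None = None
    seed: int = 0
    buffer_m: float = 1500.0
    tau0: float = 0.1

    def __post_init__(self) -> None:
        if self.n_ants <= 0 or self.n_iterations <= 0 or self.jump_radius <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.rho < 1:
            raise ValueError(f"evaporation rho must be in (0, 1), got {self.rho}")
        if not self.buffer_m > 0:
            raise ValueError("buffer_m must be positive")


@dataclass
class PheromoneField:
    tau: GridRaster
    visits: GridRaster
    region: np.ndarray  # boolean search-region mask
    start: tuple[int, int]
    end: tuple[int, int]
    success_fraction: list[float] = field(default_factory=list)

    @property
    def total_mass(self) -> float:
        return float(self.tau.values[self.region].sum())


def search_region(path: Path, grid: GridRaster, buffer_m: float = 1500.0) -> GridRaster:
    """Cells whose centres lie within ``buffer_m`` of the corridor skeleton."""
    if not path.cells:
        raise ValueError("path is empty")
    if buffer_m < grid.cell_size:
        raise ValueError(
            f"buffer ({buffer_m} m) narrower than one cell ({grid.cell_size} m)"
        )
    on_path = np.zeros(grid.shape, dtype=bool)
    rows, cols = zip(*path.cells)
    on_path[list(rows), list(cols)] = True
    dist = ndimage.distance_transform_edt(~on_path, sampling=grid.cell_size)
    return grid.like((dist <= buffer_m).astype(np.uint8))


def _resistance_threshold(resistance: GridRaster, region: np.ndarray, q: float) -> float:
    vals = resistance.values[region & resistance.valid_mask()]
    return float(np.quantile(vals.astype(float), q))


def direction_layer(
    resistance: GridRaster, region: np.ndarray, end: tuple[int, int]
) -> np.ndarray:
    """Per-cell direction code (0..7) of the cost-distance flow toward ``end``.

    Computed as the backlink direction of a least-cost accumulation seeded
    at the end terminal and restricted to the search region; cells without
    a defined direction (the end itself, unreachable cells) get code 8
    (unconstrained).
    """
    from .mcr import cost_distance

    nrows, ncols = resistance.shape
    masked = resistance.like(
        np.where(region, resistance.values.astype(float), np.nan)
    )
    surf = cost_distance(masked, [end])
    layer = np.full(nrows * ncols, 8, dtype=np.int8)
    has_pred = surf.predecessors >= 0
    nodes = np.nonzero(has_pred)[0]
    preds = surf.predecessors[nodes]
    dr = preds // ncols - nodes // ncols
    dc = preds % ncols - nodes % ncols
    for k, (orow, ocol) in enumerate(_OFFSETS):
        layer[nodes[(dr == orow) & (dc == ocol)]] = k
    return layer.reshape(nrows, ncols)


def transition_probabilities(
    cell: tuple[int, int],
    prev_dir: int,
    visited: np.ndarray,
    tau: np.ndarray,
    resistance: np.ndarray,
    region: np.ndarray,
    params: AntParams,
    threshold: float,
    dir_layer: np.ndarray | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray, bool]:
    """Admissible moves and their probabilities for one ant.

    Returns (candidate cells, probabilities, jumped).  Admissible moves are
    unvisited in-region 8-neighbours within 90° of both the previous step
    and the directional layer (when given); when none of them is at or
    below the high-resistance ``threshold``, the candidate set becomes the
    unvisited region cells within ``params.jump_radius`` (Chebyshev) and
    the choice is uniform.  An empty result means the ant is abandoned.
    """
    nrows, ncols = region.shape
    r, c = cell
    cand: list[tuple[int, int]] = []
    weights: list[float] = []
    flow = 8 if dir_layer is None else int(dir_layer[r, c])
    for k in range(8):
        if not (_ALLOWED[prev_dir, k] and _ALLOWED[flow, k]):
            continue
        nr, nc = r + int(_OFFSETS[k, 0]), c + int(_OFFSETS[k, 1])
        if not (0 <= nr < nrows and 0 <= nc < ncols):
            continue
        if not region[nr, nc] or visited[nr, nc]:
            continue
        if resistance[nr, nc] > threshold:
            continue
        cand.append((nr, nc))
        weights.append(
            tau[nr, nc] ** params.alpha * (1.0 / resistance[nr, nc]) ** params.beta
        )
    if cand:
        w = np.asarray(weights)
        total = w.sum()
        if total > 0:
            return cand, w / total, False
    # jump: uniform over unvisited region cells within the Chebyshev radius
    jr = params.jump_radius
    r0, r1 = max(0, r - jr), min(nrows, r + jr + 1)
    c0, c1 = max(0, c - jr), min(ncols, c + jr + 1)
    window = region[r0:r1, c0:c1] & ~visited[r0:r1, c0:c1]
    jr_rows, jr_cols = np.nonzero(window)
    cand = [(int(rr) + r0, int(cc) + c0) for rr, cc in zip(jr_rows, jr_cols)
            if (rr + r0, cc + c0) != (r, c)]
    if not cand:
        return [], np.array([]), True
    return cand, np.full(len(cand), 1.0 / len(cand)), True


def run_colony(
    resistance: GridRaster,
    region: GridRaster | np.ndarray,
    start: tuple[int, int],
    end: tuple[int, int],
    params: AntParams,
) -> PheromoneField:
    """Run the colony and return the accumulated pheromone field.

    Ants of one iteration advance in lock-step (the pheromone field is
    frozen within an iteration, so their walks are independent); an ant
    succeeds on entering the 8-neighbourhood of the end cell.
    """
    region_mask = region.values.astype(bool) if isinstance(region, GridRaster) else \
        np.asarray(region, dtype=bool)
    nrows, ncols = resistance.shape
    if start == end:
        raise ValueError("start and end terminals coincide")
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r < nrows and 0 <= c < ncols and region_mask[r, c]):
            raise ValueError(f"{name} terminal {r, c} outside the search region")
    res = resistance.values.astype(float)
    if np.any(res[region_mask] <= 0) or not np.all(np.isfinite(res[region_mask])):
        raise ValueError("resistance must be finite and positive inside the region")

    threshold = _resistance_threshold(resistance, region_mask, params.jump_threshold)
    flow = direction_layer(resistance, region_mask, end)
    flow_allowed = _ALLOWED[flow.ravel()]  # (ncells, 9->8) admissibility
    max_steps = params.max_steps
    if max_steps is None:
        cheb = max(abs(end[0] - start[0]), abs(end[1] - start[1]))
        max_steps = 8 * cheb + 80

    rng = np.random.default_rng(params.seed)
    tau = np.where(region_mask, params.tau0, 0.0)
    visits = np.zeros((nrows, ncols), dtype=np.int64)
    inv_res_beta = np.zeros_like(res)
    inside = region_mask & (res > 0)
    inv_res_beta[inside] = (1.0 / res[inside]) ** params.beta
    low_res = region_mask & (res <= threshold)
    cell = resistance.cell_size
    success_fraction: list[float] = []
    any_success = False

    n = params.n_ants
    flat_off = _OFFSETS[:, 0] * ncols + _OFFSETS[:, 1]

    for _ in range(params.n_iterations):
        tau_a = tau**params.alpha
        pos_r = np.full(n, start[0])
        pos_c = np.full(n, start[1])
        prev_dir = np.full(n, 8)
        active = np.ones(n, dtype=bool)
        success = np.zeros(n, dtype=bool)
        cost = np.zeros(n)
        visited = np.zeros((n, nrows, ncols), dtype=bool)
        visited[:, start[0], start[1]] = True
        # ants starting adjacent to the end succeed immediately
        if max(abs(start[0] - end[0]), abs(start[1] - end[1])) <= 1:
            success[:] = True
            active[:] = False

        for _step in range(max_steps):
            idx = np.nonzero(active)[0]
            if idx.size == 0:
                break
            nr = pos_r[idx, None] + _OFFSETS[None, :, 0]
            nc = pos_c[idx, None] + _OFFSETS[None, :, 1]
            inb = (nr >= 0) & (nr < nrows) & (nc >= 0) & (nc < ncols)
            nrc = np.clip(nr, 0, nrows - 1)
            ncc = np.clip(nc, 0, ncols - 1)
            ok = inb & _ALLOWED[prev_dir[idx]][:, :8]
            ok &= flow_allowed[pos_r[idx] * ncols + pos_c[idx]][:, :8]
            ok &= ~visited[idx[:, None], nrc, ncc]
            ok &= low_res[nrc, ncc]
            w = np.where(ok, tau_a[nrc, ncc] * inv_res_beta[nrc, ncc], 0.0)
            row_tot = w.sum(axis=1)
            normal = row_tot > 0

            # vectorized kernel sampling for ants with admissible moves
            u = rng.random(idx.size)
            cum = np.cumsum(w, axis=1)
            pick = (cum < (u * row_tot)[:, None]).sum(axis=1)
            pick = np.minimum(pick, 7)

            new_r = pos_r[idx].copy()
            new_c = pos_c[idx].copy()
            new_dir = prev_dir[idx].copy()
            step_cost = np.zeros(idx.size)
            dead = np.zeros(idx.size, dtype=bool)

            sel = np.nonzero(normal)[0]
            if sel.size:
                kr = nrc[sel, pick[sel]]
                kc = ncc[sel, pick[sel]]
                d = _STEP_LEN[pick[sel]] * cell
                step_cost[sel] = d * (res[pos_r[idx[sel]], pos_c[idx[sel]]] + res[kr, kc]) / 2.0
                new_r[sel] = kr
                new_c[sel] = kc
                new_dir[sel] = pick[sel]

            # jumping ants, handled one by one (rare)
            for a in np.nonzero(~normal)[0]:
                ant = idx[a]
                # uniform jump set: unvisited region cells within jump_radius
                jr = params.jump_radius
                r, c = pos_r[ant], pos_c[ant]
                r0, r1 = max(0, r - jr), min(nrows, r + jr + 1)
                c0, c1 = max(0, c - jr), min(ncols, c + jr + 1)
                window = region_mask[r0:r1, c0:c1] & ~visited[ant, r0:r1, c0:c1]
                jrr, jcc = np.nonzero(window)
                if jrr.size == 0:
                    dead[a] = True
                    continue
                j = int(rng.integers(jrr.size))
                tr, tc = int(jrr[j]) + r0, int(jcc[j]) + c0
                d = np.hypot(tr - r, tc - c) * cell
                step_cost[a] = d * (res[r, c] + res[tr, tc]) / 2.0
                new_r[a] = tr
                new_c[a] = tc
                new_dir[a] = 8  # jumps reset the direction memory

            moved = ~dead
            mi = idx[moved]
            pos_r[mi] = new_r[moved]
            pos_c[mi] = new_c[moved]
            prev_dir[mi] = new_dir[moved]
            cost[mi] += step_cost[moved]
            visited[mi, pos_r[mi], pos_c[mi]] = True
            active[idx[dead]] = False  # abandoned ants deposit nothing

            done = (np.abs(pos_r[mi] - end[0]) <= 1) & (np.abs(pos_c[mi] - end[1]) <= 1)
            success[mi[done]] = True
            active[mi[done]] = False

        # global pheromone update: evaporate, then successful ants deposit
        # Q/L on the passable (below-threshold) cells they visited
        tau *= 1.0 - params.rho
        for ant in np.nonzero(success)[0]:
            length = cost[ant] if cost[ant] > 0 else cell
            tau[visited[ant] & low_res] += params.deposit / length
        visits += visited.sum(axis=0)
        success_fraction.append(float(success.mean()))
        any_success = any_success or bool(success.any())

    if not any_success:
        raise RuntimeError(
            "no ant reached the target in any iteration; increase max_steps "
            "or jump_radius, or widen the search buffer"
        )
    return PheromoneField(
        tau=resistance.like(tau),
        visits=resistance.like(visits),
        region=region_mask,
        start=start,
        end=end,
        success_fraction=success_fraction,
    )


def deposit_mass(field: PheromoneField, params: AntParams) -> np.ndarray:
    """Ant-deposited pheromone: tau net of the decayed initial floor.

    The colony starts from a uniform floor tau0 which decays to
    tau0·(1−rho)^T; subtracting it isolates the mass the ants actually
    left, which is what encodes corridor position and width.
    """
    floor = params.tau0 * (1.0 - params.rho) ** params.n_iterations
    return np.where(field.region, np.maximum(field.tau.values - floor, 0.0), 0.0)


def filter_pheromone_points(
    field: PheromoneField, grid: GridRaster | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Visited cells with above-average pheromone, as weighted points.

    The global average is taken over visited cells; cells with tau strictly
    above it are returned as (N, 2) centre coordinates with their tau as
    weights.  Ties (a perfectly flat field) yield an empty set.
    """
    grid = grid if grid is not None else field.tau
    visited = field.visits.values > 0
    if not visited.any():
        raise ValueError("pheromone field has no visited cells")
    tau = field.tau.values.astype(float)
    mean = tau[visited].mean()
    keep = visited & (tau > mean)
    rows, cols = np.nonzero(keep)
    if rows.size == 0:
        import warnings

        warnings.warn("all pheromone values equal; no point exceeds the mean",
                      stacklevel=2)
        return np.empty((0, 2)), np.empty(0)
    xs = grid.origin[0] + (cols + 0.5) * grid.cell_size
    ys = grid.origin[1] - (rows + 0.5) * grid.cell_size
    return np.column_stack([xs, ys]), tau[rows, cols]
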