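"""Minimum cumulative resistance (MCR) cost surfaces and corridor skeletons.

The MCR of a cell is the least, over 8-connected paths from any ecological
source, of the accumulated distance-weighted resistance

    MCR = min Σ D_ij · R_i

with the standard GIS step-cost convention: each step between adjacent
cells a and b costs d · (R_a + R_b) / 2 where d is the centre-to-centre
distance (cell_size orthogonally, cell_size·√2 diagonally).  Any strictly
increasing transform of the accumulation leaves the minimizing paths
unchanged, so the identity is used.

Shortest paths are computed with Dijkstra's algorithm on the sparse cell
adjacency graph; corridor skeletons connect source terminals with the
union of the cost-weighted minimum spanning tree and each terminal's
k-nearest (by cost) neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from .grid import GridRaster
from .sources import SourceSet

_SQRT2 = np.sqrt(2.0)


@dataclass
class CostSurface:
    """Accumulated-cost raster with backlinks for path tracing."""

    mcr: GridRaster
    predecessors: np.ndarray  # flat node index of the predecessor, -9999 = none
    source_id: GridRaster  # id of the nearest source by cost (-1 unreached)
    n_unreachable: int


@dataclass
class Path:
    cells: list[tuple[int, int]]  # (row, col), consecutive cells 8-adjacent
    total_cost: float
    endpoints: tuple[int, int] = (-1, -1)  # source ids

    def __len__(self) -> int:
        return len(self.cells)

    def xy(self, grid: GridRaster) -> list[tuple[float, float]]:
        return [grid.cell_center(r, c) for r, c in self.cells]

    def cell_set(self) -> set[tuple[int, int]]:
        return set(self.cells)


def _validate_resistance(resistance: GridRaster) -> np.ndarray:
    valid = resistance.valid_mask()
    vals = resistance.values.astype(float)
    if np.any(vals[valid] <= 0):
        raise ValueError("resistance must be strictly positive on traversable cells")
    return valid


def _adjacency(resistance: GridRaster, valid: np.ndarray) -> coo_matrix:
    """Sparse 8-neighbour graph with endpoint-average step costs."""
    nrows, ncols = resistance.shape
    n = nrows * ncols
    res = np.where(valid, resistance.values.astype(float), np.nan)
    rows_i, cols_i, weights = [], [], []
    # forward offsets only; the graph is used undirected
    for dr, dc, dist in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, _SQRT2), (1, -1, _SQRT2)):
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a = res[r0, c0]
        b = res[r1, c1]
        ok = np.isfinite(a) & np.isfinite(b)
        idx = np.arange(n).reshape(nrows, ncols)
        ia = idx[r0, c0][ok]
        ib = idx[r1, c1][ok]
        w = dist * resistance.cell_size * (a[ok] + b[ok]) / 2.0
        rows_i.append(ia)
        cols_i.append(ib)
        weights.append(w)
    return coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    )


def _seed_cells(sources: SourceSet | list) -> list[tuple[int, list[tuple[int, int]]]]:
    """Normalize the seed argument to [(source_id, [(row, col), ...]), ...]."""
    if isinstance(sources, SourceSet):
        out = []
        for p in sources:
            cells = [tuple(c) for c in p.cells] if getattr(p, "cells", None) is not None \
                else [p.centre_cell]
            out.append((p.id, cells))
        return out
    out = []
    for i, item in enumerate(sources):
        if isinstance(item, tuple) and len(item) == 2 and np.isscalar(item[0]):
            out.append((i, [item]))
        else:
            out.append((i, [tuple(c) for c in item]))
    return out


def cost_distance(resistance: GridRaster, sources: SourceSet | list) -> CostSurface:
    """Multi-source Dijkstra accumulation over the resistance raster.

    ``sources`` may be a :class:`SourceSet` (all patch cells are zero-cost
    seeds) or a list of (row, col) terminals.  Unreachable cells get
    infinite cost and are counted.
    """
    valid = _validate_resistance(resistance)
    seeds = _seed_cells(sources)
    if not seeds:
        raise ValueError("need at least one source")
    nrows, ncols = resistance.shape
    graph = _adjacency(resistance, valid)
    seed_nodes = []
    seed_ids = []
    for sid, cells in seeds:
        for r, c in cells:
            if not (0 <= r < nrows and 0 <= c < ncols):
                raise ValueError(f"source cell {(r, c)} outside the grid")
            seed_nodes.append(r * ncols + c)
            seed_ids.append(sid)
    dist, pred, src = dijkstra(
        graph, directed=False, indices=seed_nodes, return_predecessors=True,
        min_only=True,
    )
    mcr_vals = dist.reshape(nrows, ncols)
    mcr_vals = np.where(valid, mcr_vals, np.inf)
    node_to_sid = dict(zip(seed_nodes, seed_ids))
    sid_flat = np.array([node_to_sid.get(s, -1) for s in src]) if len(src) else src
    source_id = np.where(np.isfinite(mcr_vals), sid_flat.reshape(nrows, ncols), -1)
    n_unreachable = int(np.sum(valid & ~np.isfinite(mcr_vals)))
    if n_unreachable:
        warnings.warn(f"{n_unreachable} cells unreachable from any source",
                      stacklevel=2)
    return CostSurface(
        mcr=resistance.like(mcr_vals),
        predecessors=pred,
        source_id=resistance.like(source_id.astype(np.int32)),
        n_unreachable=n_unreachable,
    )


def least_cost_path(cost: CostSurface, target: tuple[int, int]) -> Path:
    """Backlink-traced least-cost path from the target cell to its source."""
    nrows, ncols = cost.mcr.shape
    r, c = target
    if not np.isfinite(cost.mcr.values[r, c]):
        raise ValueError(f"target cell {target} is unreachable")
    node = r * ncols + c
    cells = [(r, c)]
    while cost.predecessors[node] >= 0:
        node = int(cost.predecessors[node])
        cells.append((node // ncols, node % ncols))
    cells.reverse()
    return Path(cells=cells, total_cost=float(cost.mcr.values[r, c]))


def corridor_network(
    resistance: GridRaster,
    sources: SourceSet,
    k_neighbors: int = 2,
    duplicate_overlap: float = 0.9,
) -> list[Path]:
    """Least-cost paths between source terminals.

    Candidate edges are the union of the cost-weighted minimum spanning
    tree over the terminals and each terminal's ``k_neighbors`` nearest
    (by cost) neighbours; one least-cost path is traced per edge, and
    paths sharing at least ``duplicate_overlap`` of their cells are
    merged (the cheaper one is kept).
    """
    if len(sources) < 2:
        raise ValueError("need at least two sources for a corridor network")
    terminals = sources.terminals()
    ids = [p.id for p in sources]
    n = len(terminals)
    nrows, ncols = resistance.shape

    # one single-source Dijkstra per terminal, keeping predecessors
    costs = np.full((n, n), np.inf)
    surfaces: list[CostSurface] = []
    for i, (r, c) in enumerate(terminals):
        surf = cost_distance(resistance, [(r, c)])
        surfaces.append(surf)
        for j, (rj, cj) in enumerate(terminals):
            costs[i, j] = surf.mcr.values[rj, cj]

    reachable = np.isfinite(costs).all(axis=1)
    for i in np.nonzero(~reachable)[0]:
        warnings.warn(
            f"source {ids[i]} unreachable from some terminals; excluded",
            stacklevel=2,
        )
    keep = np.nonzero(reachable)[0]
    if len(keep) < 2:
        raise ValueError("fewer than two mutually reachable sources")

    sub = costs[np.ix_(keep, keep)]
    mst = minimum_spanning_tree(np.triu(sub)).tocoo()
    edges = {(int(keep[i]), int(keep[j])) for i, j in zip(mst.row, mst.col)}
    for a_pos, a in enumerate(keep):
        order = np.argsort(sub[a_pos])
        added = 0
        for b_pos in order:
            b = int(keep[b_pos])
            if b == a or not np.isfinite(sub[a_pos, b_pos]):
                continue
            edges.add((min(int(a), b), max(int(a), b)))
            added += 1
            if added >= k_neighbors:
                break

    paths: list[Path] = []
    for i, j in sorted(edges):
        path = least_cost_path(surfaces[i], terminals[j])
        path.endpoints = (ids[i], ids[j])
        paths.append(path)

    # merge geometric duplicates (≥ duplicate_overlap shared cells)
    merged: list[Path] = []
    for p in sorted(paths, key=lambda p: p.total_cost):
        cells = p.cell_set()
        dup = any(
            len(cells & q.cell_set()) / max(len(cells), 1) >= duplicate_overlap
            for q in merged
        )
        if not dup:
            merged.append(p)
    return merged
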