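"""Per-cell ecosystem-service operators.

Five services drive source identification in the pipeline: gas regulation
(net primary productivity), habitat maintenance (InVEST-style habitat
quality), soil conservation (RUSLE overlay), water supply (annual water
balance) and food supply (yearbook grain output spread over cropland in
proportion to NDVI).  Each operator is a pure per-cell map on aligned
rasters; nodata in any input propagates to the output.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grid import GridRaster, check_aligned


def _combine_nodata(out: np.ndarray, *rasters: GridRaster) -> np.ndarray:
    valid = np.ones(out.shape, dtype=bool)
    for r in rasters:
        valid &= r.valid_mask()
    result = np.where(valid, out, np.nan)
    return result


def compute_npp(apar: GridRaster, epsilon: GridRaster) -> GridRaster:
    """Net primary productivity: NPP = APAR × ε (light-use efficiency)."""
    check_aligned(apar, epsilon)
    npp = apar.values.astype(float) * epsilon.values.astype(float)
    return apar.like(_combine_nodata(npp, apar, epsilon))


def compute_habitat_quality(
    habitat: GridRaster,
    degradation: GridRaster,
    k: float = 0.5,
    z: float = 2.0,
) -> GridRaster:
    """Habitat quality Q = H · (1 − D^z / (D^z + k^z)).

    ``habitat`` is the per-cell habitat attribute of the land-use class
    (0–1), ``degradation`` the habitat-degradation score D in [0, 1], ``k``
    the half-saturation constant (Q drops to H/2 where D = k) and ``z`` the
    saturation exponent.
    """
    if not k > 0:
        raise ValueError(f"half-saturation constant k must be positive, got {k}")
    check_aligned(habitat, degradation)
    d = degradation.values.astype(float)
    finite_d = d[degradation.valid_mask()]
    if finite_d.size and (finite_d.min() < 0 or finite_d.max() > 1):
        raise ValueError("degradation D must lie in [0, 1]")
    dz = np.power(d, z)
    q = habitat.values.astype(float) * (1.0 - dz / (dz + k**z))
    return habitat.like(_combine_nodata(q, habitat, degradation))


def compute_soil_conservation(
    erodibility: GridRaster,
    erosivity: GridRaster,
    ls: GridRaster,
    cover: GridRaster,
    practice: GridRaster,
) -> GridRaster:
    """Soil conservation A = K · R · LS · (1 − C·P) from RUSLE factors.

    K: soil erodibility, R: rainfall erosivity, LS: slope length/steepness,
    C: cover management in [0, 1], P: support practice in [0, 1].
    """
    check_aligned(erodibility, erosivity, ls, cover, practice)
    for name, r in (("C", cover), ("P", practice)):
        v = r.finite_values()
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError(f"RUSLE factor {name} must lie in [0, 1]")
    a = (
        erodibility.values.astype(float)
        * erosivity.values.astype(float)
        * ls.values.astype(float)
        * (1.0 - cover.values.astype(float) * practice.values.astype(float))
    )
    return erodibility.like(
        _combine_nodata(a, erodibility, erosivity, ls, cover, practice)
    )


def compute_water_yield(
    precipitation: GridRaster,
    evapotranspiration: GridRaster,
    runoff: GridRaster,
    clip_negative: bool = False,
) -> GridRaster:
    """Annual water supply W = P − ET − Q (all in mm).

    Negative balances are physically suspect but retained by default (and
    counted in a warning) so that input problems stay visible; pass
    ``clip_negative=True`` to floor at zero.
    """
    check_aligned(precipitation, evapotranspiration, runoff)
    w = (
        precipitation.values.astype(float)
        - evapotranspiration.values.astype(float)
        - runoff.values.astype(float)
    )
    w = _combine_nodata(w, precipitation, evapotranspiration, runoff)
    n_deficit = int(np.sum(w < 0))
    if n_deficit:
        warnings.warn(
            f"water yield negative in {n_deficit} cells (ET + runoff exceed "
            "precipitation)",
            stacklevel=2,
        )
        if clip_negative:
            w = np.where(w < 0, 0.0, w)
    return precipitation.like(w)


def allocate_food_supply(
    ndvi: GridRaster,
    cropland_mask: GridRaster,
    region_mask: GridRaster,
    region_output: dict[int, float],
) -> GridRaster:
    """Spread per-region grain output over cropland in proportion to NDVI.

    Cropland cell i of region r receives ``region_output[r] · NDVI_i / Σ
    NDVI`` where the sum runs over the region's cropland; non-cropland
    cells get 0.  Per-region totals are conserved exactly.
    """
    check_aligned(ndvi, cropland_mask, region_mask)
    crop = cropland_mask.values.astype(bool)
    regions = region_mask.values
    nv = ndvi.values.astype(float)
    if np.any(nv[crop & ndvi.valid_mask()] < 0):
        raise ValueError("NDVI must be nonnegative on cropland")
    out = np.zeros(ndvi.shape, dtype=float)
    for region_id, total in region_output.items():
        if total < 0:
            raise ValueError(f"region {region_id} output is negative")
        sel = crop & (regions == region_id) & ndvi.valid_mask()
        ndvi_sum = nv[sel].sum()
        if total > 0 and ndvi_sum == 0:
            raise ValueError(
                f"region {region_id} has output {total} but zero total NDVI "
                "on cropland"
            )
        if ndvi_sum > 0:
            out[sel] = total * nv[sel] / ndvi_sum
    return ndvi.like(_combine_nodata(out, ndvi, cropland_mask, region_mask))
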