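"""Resistance-surface construction.

Basic resistance: each of six environmental factors (land cover, slope,
altitude, vegetation coverage, soil thickness, bedrock type) is classified
to a basic resistance coefficient, and the classified layers are combined
as a weighted sum.  Weights come either from a shipped default table or are
recomputed from the data by the entropy weight method.

Sensitivity correction: an ecological sensitivity index ESI = a·RDI +
b·KCI + c·SEI (rocky desertification, karst collapse, soil erosion) is
min-max standardized and each cell's basic resistance is scaled by the
ratio of its standardized sensitivity to the regional mean, so that cells
of average sensitivity keep their basic resistance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import FactorStack, GridRaster, check_aligned

#: Default per-factor classification: value interval or category ->
#: basic resistance coefficient.  Intervals are left-closed, right-open;
#: the top class is closed above.
DEFAULT_CLASSIFICATION: dict[str, object] = {
    "land_cover": {
        "Forest land": 5,
        "Grassland": 10,
        "Garden Land": 20,
        "Cultivated land": 30,
        "Waters": 50,
        "Unutilized land": 70,
        "Traffic land": 80,
        "Construction Land": 100,
    },
    "slope": [(0, 15, 10), (15, 25, 30), (25, 35, 50), (35, None, 80)],
    "altitude": [(None, 800, 10), (800, 1300, 30), (1300, 1500, 50), (1500, None, 80)],
    "vegetation_coverage": [
        (None, 35, 10),
        (35, 50, 30),
        (50, 65, 50),
        (65, None, 80),
    ],
    "soil_thickness": [(None, 10, 10), (10, 30, 40), (30, None, 70)],
    "bedrock": {
        "Non-carbonate rock": 10,
        "Limestone": 30,
        "Interformation of limestone and dolomite": 50,
        "Dolomite": 70,
        "Carbonate rock with clastic rock": 90,
    },
}

#: Default factor weights (entropy-weight values for the reference study
#: area); they sum to 1.
DEFAULT_WEIGHTS: dict[str, float] = {
    "land_cover": 0.1671,
    "slope": 0.1198,
    "altitude": 0.2054,
    "vegetation_coverage": 0.1436,
    "soil_thickness": 0.1496,
    "bedrock": 0.2145,
}

#: Default sensitivity-index weights (a, b, c) for RDI, KCI, SEI.
DEFAULT_ESI_WEIGHTS: tuple[float, float, float] = (0.483, 0.282, 0.235)


@dataclass
class ClassificationTable:
    """Per-factor classification rules and factor weights.

    ``rules[name]`` is either a dict (categorical factor: category value ->
    coefficient) or an ordered list of ``(low, high, coefficient)`` tuples
    with ``None`` for an open end; intervals are [low, high).
    """

    rules: dict[str, object] = field(
        default_factory=lambda: dict(DEFAULT_CLASSIFICATION)
    )
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if self.weights and not np.isclose(total, 1.0, atol=1e-3):
            raise ValueError(f"factor weights must sum to 1, got {total}")


def classify_factor(
    factor: GridRaster,
    rule: object,
    categories: dict[int, str] | None = None,
) -> GridRaster:
    """Map a factor raster to its basic resistance coefficients.

    ``rule`` is one entry of :class:`ClassificationTable`.  For categorical
    factors the raster may hold integer codes with ``categories`` giving
    the code -> category-name mapping, or the rule keys may be the codes
    themselves.  Every observed value must map to a class.
    """
    valid = factor.valid_mask()
    out = np.full(factor.shape, np.nan)
    vals = factor.values
    if isinstance(rule, dict):
        lookup: dict[object, float] = dict(rule)
        if categories:
            lookup = {code: rule[name] for code, name in categories.items()}
        unmapped = set()
        for key, coeff in lookup.items():
            out[valid & (vals == key)] = coeff
        missing = valid & np.isnan(out)
        if missing.any():
            unmapped = set(np.unique(vals[missing]).tolist())
            raise ValueError(
                f"unmapped categories in factor raster: {sorted(unmapped)}"
            )
    else:
        v = vals.astype(float)
        assigned = np.zeros(factor.shape, dtype=bool)
        for low, high, coeff in rule:
            sel = valid & ~assigned
            if low is not None:
                sel &= v >= low
            if high is not None:
                sel &= v < high
            out[sel] = coeff
            assigned |= sel
        missing = valid & ~assigned
        if missing.any():
            raise ValueError(
                "factor values outside every class interval: "
                f"{sorted(np.unique(vals[missing]).tolist())[:10]}"
            )
    return factor.like(out)


def classify_stack(
    factors: FactorStack,
    table: ClassificationTable,
    categories: dict[str, dict[int, str]] | None = None,
) -> FactorStack:
    """Classify every factor of a stack with its table entry."""
    categories = categories or {}
    out: dict[str, GridRaster] = {}
    for name in factors:
        if name not in table.rules:
            raise ValueError(f"no classification rule for factor {name!r}")
        out[name] = classify_factor(
            factors[name], table.rules[name], categories.get(name)
        )
    return FactorStack(out)


def entropy_weights(samples: np.ndarray) -> np.ndarray:
    """Entropy-weight method: objective factor weights from a sample matrix.

    Rows are observations (cells), columns factors.  Columns are min-shifted
    to be nonnegative and normalized to proportions p_ij; the entropy of
    column j is e_j = −(ln n)⁻¹ Σ_i p_ij ln p_ij (with 0·ln 0 = 0), its
    divergence d_j = 1 − e_j, and the weight w_j = d_j / Σ d_j.  A constant
    column has zero divergence and therefore zero weight.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D sample matrix with at least 2 rows")
    n = x.shape[0]
    x = x - x.min(axis=0, keepdims=True)  # min-shift to nonnegative
    col_sum = x.sum(axis=0)
    divergence = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if col_sum[j] == 0:  # constant column: no information
            continue
        p = x[:, j] / col_sum[j]
        nz = p > 0
        e = -np.sum(p[nz] * np.log(p[nz])) / np.log(n)
        divergence[j] = 1.0 - e
    total = divergence.sum()
    if total <= 0:
        raise ValueError("no information in any factor (all columns constant)")
    return divergence / total


def base_resistance(classified: FactorStack, weights: dict[str, float]) -> GridRaster:
    """Weighted sum of classified factor coefficients, Σ_j w_j · coeff_j."""
    if set(weights) != set(classified.names):
        raise ValueError(
            f"weights {sorted(weights)} do not match factors {sorted(classified.names)}"
        )
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-3):
        raise ValueError(f"weights must sum to 1, got {total}")
    ref = classified.reference
    acc = np.zeros(ref.shape, dtype=float)
    for name in classified:
        acc += weights[name] * classified[name].values.astype(float)
    acc = np.where(classified.valid_mask(), acc, np.nan)
    return ref.like(acc)


@dataclass
class SensitivityStack:
    """Ecological sensitivity index and its standardization."""

    esi: GridRaster
    esi_std: GridRaster
    esi_min: float
    esi_max: float
    weights: tuple[float, float, float]
    constant: bool  # True when ESI has zero range (standardization undefined)


def sensitivity_index(
    rdi: GridRaster,
    kci: GridRaster,
    sei: GridRaster,
    weights: tuple[float, float, float] = DEFAULT_ESI_WEIGHTS,
) -> SensitivityStack:
    """ESI = a·RDI + b·KCI + c·SEI, then min-max standardized.

    RDI, KCI, SEI are the rocky desertification, karst collapse and soil
    erosion indices rescaled to [0, 1]; (a, b, c) must sum to 1.
    """
    a, b, c = weights
    if not np.isclose(a + b + c, 1.0, atol=1e-3):
        raise ValueError(f"sensitivity weights must sum to 1, got {a + b + c}")
    check_aligned(rdi, kci, sei)
    esi_vals = (
        a * rdi.values.astype(float)
        + b * kci.values.astype(float)
        + c * sei.values.astype(float)
    )
    valid = rdi.valid_mask() & kci.valid_mask() & sei.valid_mask()
    esi_vals = np.where(valid, esi_vals, np.nan)
    esi = rdi.like(esi_vals)
    finite = esi.finite_values()
    if finite.size == 0:
        raise ValueError("sensitivity indices are all nodata")
    esi_min, esi_max = float(finite.min()), float(finite.max())
    constant = np.isclose(esi_min, esi_max)
    if constant:
        std_vals = np.where(valid, 1.0, np.nan)
    else:
        std_vals = (esi_vals - esi_min) / (esi_max - esi_min)
    return SensitivityStack(esi, rdi.like(std_vals), esi_min, esi_max,
                            (a, b, c), constant)


@dataclass
class ResistanceSurface:
    """Basic resistance R and sensitivity-corrected resistance R_i."""

    basic: GridRaster
    corrected: GridRaster


def correct_resistance(
    basic: GridRaster,
    stack: SensitivityStack,
    use_standardized: bool = True,
) -> ResistanceSurface:
    """R_i = R × ESI_std / mean(ESI_std) (ratio-to-mean correction).

    A cell of exactly average sensitivity keeps its basic resistance; more
    sensitive cells are penalized proportionally.  With a spatially
    constant ESI the correction is a documented no-op.  Passing
    ``use_standardized=False`` uses the raw ESI in the ratio instead.
    """
    check_aligned(basic, stack.esi)
    if stack.constant:
        warnings.warn(
            "ESI is spatially constant; resistance correction is a no-op",
            stacklevel=2,
        )
        return ResistanceSurface(basic, basic.copy())
    numerator = stack.esi_std if use_standardized else stack.esi
    num_vals = numerator.values.astype(float)
    valid = basic.valid_mask() & numerator.valid_mask()
    mean = float(num_vals[valid].mean())
    assert mean > 0, "min-max standardized ESI has positive mean by construction"
    corrected = np.where(valid, basic.values.astype(float) * num_vals / mean, np.nan)
    return ResistanceSurface(basic, basic.like(corrected))
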