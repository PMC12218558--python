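"""Per-pixel linear NDVI trends and class maps.

The trend statistic is the ordinary least-squares slope of annual NDVI on
the time index i = 1..n,

    slope = (n * sum(i * y_i) - sum(i) * sum(y_i))
            / (n * sum(i^2) - sum(i)^2)

in NDVI units per year.  Slopes are binned into five trend classes and
annual NDVI into six coverage classes (bare .. high coverage); class
proportions per year and their own linear rates summarize the maps.

Bin conventions (exact boundary membership is part of the contract):

* trend:    obvious degradation  slope <= -0.0019
            mild degradation     (-0.0019, -0.0010)
            basically stable     [-0.0010, -0.0002)
            slight improvement   [-0.0002,  0.0006)
            significant improvement  slope >= 0.0006
* coverage: left-open right-closed NDVI bins at 0, 0.2, 0.4, 0.6, 0.8, 1;
            everything at or below 0 is bare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid, RasterStack

__all__ = [
    "TREND_CLASSES",
    "COVERAGE_CLASSES",
    "pixel_slope",
    "slope_series",
    "classify_trend",
    "classify_coverage",
    "trend_map",
    "coverage_map",
    "class_proportions",
    "proportion_trend",
    "TrendMap",
    "CoverageMap",
]

TREND_CLASSES = (
    "obvious degradation",
    "mild degradation",
    "basically stable",
    "slight improvement",
    "significant improvement",
)
_TREND_EDGES = (-0.0019, -0.0010, -0.0002, 0.0006)

COVERAGE_CLASSES = (
    "bare",
    "low coverage",
    "medium-low coverage",
    "medium coverage",
    "medium-high coverage",
    "high coverage",
)
_COVERAGE_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8)

MIN_YEARS_FOR_SLOPE = 3


@dataclass
class TrendMap:
    slope: Grid
    class_map: Grid
    class_table: pd.Series  # fraction of unmasked cells per trend class


@dataclass
class CoverageMap:
    class_map: Grid
    proportions: pd.Series  # fraction of unmasked cells per coverage class


def slope_series(values: np.ndarray, index: np.ndarray | None = None) -> float:
    """OLS slope of a 1-D series on its time index (1..n by default)."""
    y = np.asarray(values, dtype=np.float64)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two points")
    i = np.arange(1, n + 1, dtype=np.float64) if index is None else np.asarray(index, float)
    num = n * (i * y).sum() - i.sum() * y.sum()
    den = n * (i * i).sum() - i.sum() ** 2
    return float(num / den)


def pixel_slope(stack: RasterStack, min_years: int = MIN_YEARS_FOR_SLOPE) -> Grid:
    """Per-cell OLS slope of the stack on the time index.

    Cells with fewer than ``min_years`` valid years are masked; the index
    i runs over the stack positions (consecutive annual grids), so only
    the valid years of each cell enter its normal equations.
    """
    arr = stack.as_array()  # (t, r, c)
    t = len(stack)
    i = np.arange(1, t + 1, dtype=np.float64)[:, None, None]
    w = (~np.ma.getmaskarray(arr)).astype(np.float64)
    y = arr.filled(0.0)
    n = w.sum(axis=0)
    si = (w * i).sum(axis=0)
    sii = (w * i * i).sum(axis=0)
    sy = (w * y).sum(axis=0)
    siy = (w * i * y).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = n * sii - si * si
        slope = (n * siy - si * sy) / den
    bad = (n < min_years) | (den <= 0)
    slope = np.where(bad, stack.geometry.nodata, slope)
    return stack.geometry.copy_with(slope, bad)


def classify_trend(theta) -> np.ndarray | str:
    """Trend class of a slope value (scalar or array)."""
    arr = np.asarray(theta, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite slope value")
    e = _TREND_EDGES
    code = np.select(
        [arr <= e[0], arr < e[1], arr < e[2], arr < e[3]],
        [0, 1, 2, 3],
        default=4,
    )
    if np.isscalar(theta) or arr.ndim == 0:
        return TREND_CLASSES[int(code)]
    return code


def classify_coverage(ndvi) -> np.ndarray | str:
    """Coverage class of an NDVI value (scalar or array) in [-1, 1]."""
    arr = np.asarray(ndvi, dtype=np.float64)
    if np.any(~np.isfinite(arr)) or np.any(arr < -1) or np.any(arr > 1):
        raise ValueError("NDVI outside [-1, 1]")
    # left-open right-closed: value exactly at an edge joins the class below
    code = np.searchsorted(_COVERAGE_EDGES, arr, side="left")
    if np.isscalar(ndvi) or arr.ndim == 0:
        return COVERAGE_CLASSES[int(code)]
    return code


def _class_fractions(codes: np.ndarray, valid: np.ndarray, names: tuple[str, ...]) -> pd.Series:
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all cells masked")
    counts = np.bincount(codes[valid].astype(int), minlength=len(names))
    return pd.Series(counts / n, index=list(names))


def trend_map(stack: RasterStack, min_years: int = MIN_YEARS_FOR_SLOPE) -> TrendMap:
    slope = pixel_slope(stack, min_years)
    codes = np.zeros(slope.shape, dtype=np.int16)
    codes[slope.valid] = classify_trend(slope.values[slope.valid])
    cmap = slope.copy_with(codes.astype(np.float64), slope.mask.copy())
    table = _class_fractions(codes, slope.valid, TREND_CLASSES)
    return TrendMap(slope=slope, class_map=cmap, class_table=table)


def coverage_map(grid: Grid) -> CoverageMap:
    codes = np.zeros(grid.shape, dtype=np.int16)
    codes[grid.valid] = classify_coverage(grid.values[grid.valid])
    cmap = grid.copy_with(codes.astype(np.float64), grid.mask.copy())
    props = _class_fractions(codes, grid.valid, COVERAGE_CLASSES)
    return CoverageMap(class_map=cmap, proportions=props)


def class_proportions(class_map: Grid, classes: tuple[str, ...] = COVERAGE_CLASSES) -> pd.Series:
    """Fraction of unmasked cells per class code; absent classes report 0."""
    return _class_fractions(class_map.values.astype(int), class_map.valid, classes)


def proportion_trend(fractions_per_year: pd.DataFrame) -> pd.Series:
    """OLS slope of each class's percentage share on the year.

    ``fractions_per_year`` is (year x class) with fractions in [0, 1];
    rates come back in percentage points per year.
    """
    if len(fractions_per_year) < 3:
        raise ValueError("need at least three years")
    years = fractions_per_year.index.to_numpy(dtype=float)
    return fractions_per_year.apply(
        lambda col: slope_series(col.to_numpy() * 100.0, years), axis=0
    )
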