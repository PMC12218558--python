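"""Per-pixel Pearson correlation between annual NDVI and driver series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import Grid, RasterStack

__all__ = ["CorrelationMap", "pixel_correlation", "correlation_map", "sign_fractions"]

MIN_YEARS = 5


@dataclass
class CorrelationMap:
    """Per-pixel Pearson r between a driver and NDVI over one period."""

    r: Grid
    p: Grid
    n_years: Grid
    driver: str = ""
    period: tuple[int, int] | None = None


def pixel_correlation(x_series: np.ndarray, y_series: np.ndarray,
                      min_years: int = MIN_YEARS) -> float:
    """Pearson r of two 1-D annual series on their jointly valid years.

    Returns NaN (masked downstream) when fewer than ``min_years`` pairs
    are valid or either series has zero variance.
    """
    x = np.asarray(x_series, dtype=np.float64)
    y = np.asarray(y_series, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_years:
        return float("nan")
    x, y = x[ok], y[ok]
    xm, ym = x - x.mean(), y - y.mean()
    sx = (xm * xm).sum()
    sy = (ym * ym).sum()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xm * ym).sum() / np.sqrt(sx * sy))


def correlation_map(driver: RasterStack, ndvi: RasterStack,
                    min_years: int = MIN_YEARS, name: str = "",
                    period: tuple[int, int] | None = None) -> CorrelationMap:
    """Per-cell Pearson r between co-registered driver and NDVI stacks.

    Both stacks must share geometry and time index; each cell uses only
    its jointly valid years.  Two-sided p-values (t on n-2 df) are
    computed and stored but never used for masking — maps show raw r.
    """
    if len(driver) != len(ndvi) or list(driver.time_index) != list(ndvi.time_index):
        raise ValueError("driver and NDVI stacks must share their time index")
    if not driver.geometry.same_geometry(ndvi.geometry):
        raise ValueError("driver and NDVI stacks must share geometry")
    xa, ya = driver.as_array(), ndvi.as_array()
    ok = ~(np.ma.getmaskarray(xa) | np.ma.getmaskarray(ya))
    w = ok.astype(np.float64)
    x = np.where(ok, xa.filled(0.0), 0.0)
    y = np.where(ok, ya.filled(0.0), 0.0)
    n = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = x.sum(axis=0) / n
        my = y.sum(axis=0) / n
        xm = (x - mx) * w
        ym = (y - my) * w
        sxy = (xm * ym).sum(axis=0)
        sxx = (xm * xm).sum(axis=0)
        syy = (ym * ym).sum(axis=0)
        r = sxy / np.sqrt(sxx * syy)
    bad = (n < min_years) | (sxx <= 0) | (syy <= 0) | ~np.isfinite(r)
    r = np.clip(np.where(bad, 0.0, r), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.maximum(n - 2, 1)
        t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    ref = ndvi.geometry
    nodata = ref.nodata
    return CorrelationMap(
        r=ref.copy_with(np.where(bad, nodata, r), bad),
        p=ref.copy_with(np.where(bad, nodata, p), bad),
        n_years=ref.copy_with(n, bad),
        driver=name,
        period=period,
    )


def sign_fractions(cmap: CorrelationMap, threshold: float = 0.0) -> tuple[float, float]:
    """(fraction positive, fraction negative) over unmasked cells.

    Cells with r >= threshold count positive (boundary inclusive); cells
    with r < -threshold count negative.  At the default threshold 0 the
    two fractions sum to 1.
    """
    g = cmap.r
    valid = g.valid
    n = int(valid.sum())
    if n == 0:
        raise ValueError("correlation map is fully masked")
    r = g.values[valid]
    return float((r >= threshold).mean()), float((r < -threshold).mean())
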