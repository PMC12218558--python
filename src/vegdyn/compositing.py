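"""Growing-season NDVI compositing.

Sub-monthly NDVI composites (e.g. 15-day AVHRR scenes) are reduced per
month by maximum-value compositing (MVC), which suppresses cloud- and
atmosphere-depressed values, and the May-September monthly maxima are then
collapsed to one annual growing-season field — either as the mean of the
monthly maxima (default) or as the single seasonal maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Grid, RasterStack

__all__ = ["CompositeConfig", "mvc", "growing_season_ndvi", "regional_mean"]

GROWING_SEASON = (5, 6, 7, 8, 9)


@dataclass(frozen=True)
class CompositeConfig:
    """Season definition and reduction mode.

    ``monthly_max_mean`` averages the per-month MVC grids over the season;
    ``seasonal_max`` takes the single per-cell maximum over the season.
    """

    season_months: tuple[int, ...] = GROWING_SEASON
    mode: str = "monthly_max_mean"

    def __post_init__(self) -> None:
        if not self.season_months:
            raise ValueError("season_months must be nonempty")
        if self.mode not in ("monthly_max_mean", "seasonal_max"):
            raise ValueError(f"unknown compositing mode {self.mode!r}")


def mvc(composites: RasterStack) -> Grid:
    """Per-cell maximum over the unmasked composites of one month.

    A cell is masked in the output only if it is masked in every input.
    """
    if len(composites) == 0:
        raise ValueError("empty composite stack")
    arr = composites.as_array()
    out = arr.max(axis=0)
    ref = composites.geometry
    return ref.copy_with(out.filled(ref.nodata), np.ma.getmaskarray(out))


def growing_season_ndvi(monthly_max: RasterStack, config: CompositeConfig | None = None) -> Grid:
    """Collapse one season's monthly MVC grids to the annual NDVI field.

    ``monthly_max.time_index`` must carry the month numbers; a missing
    season month is an error (naming the absent months) rather than a
    silent shorter season.
    """
    config = config or CompositeConfig()
    present = set(monthly_max.time_index)
    missing = sorted(set(config.season_months) - present)
    if missing:
        raise ValueError(f"missing season months: {missing}")
    keep = [i for i, m in enumerate(monthly_max.time_index) if m in config.season_months]
    arr = monthly_max.as_array()[keep]
    if config.mode == "monthly_max_mean":
        out = arr.mean(axis=0)
        out.mask = np.ma.getmaskarray(arr).any(axis=0)  # all months required per cell
    else:
        out = arr.max(axis=0)
    ref = monthly_max.geometry
    return ref.copy_with(out.filled(ref.nodata), np.ma.getmaskarray(out))


def regional_mean(grid: Grid, mask: Grid | None = None) -> float:
    """Unweighted mean over unmasked (and in-mask, if given) cells.

    ``mask`` is an optional region raster (e.g. a watershed boundary):
    cells that are masked or zero there are excluded.
    """
    valid = grid.valid
    if mask is not None:
        if mask.shape != grid.shape:
            raise ValueError("region mask shape mismatch")
        valid = valid & mask.valid & (mask.values != 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid cells to average")
    return float(grid.values[valid].mean())
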