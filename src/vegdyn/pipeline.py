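"""End-to-end orchestration of the vegetation-dynamics analysis.

Stage order: growing-season compositing -> regional annual series ->
ordered-cluster change point -> segmentation -> per-segment trend maps,
coverage proportions and NDVI-driver correlation -> Geodetector factor and
interaction detection.  Every run writes a JSON manifest (config echo,
seeds, stage log with dropped-cell counts) plus CSV/GeoTIFF artifacts, and
is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .changepoint import AnnualSeries, analyze, segment
from .compositing import CompositeConfig, growing_season_ndvi, mvc, regional_mean
from .correlation import correlation_map, sign_fractions
from .geodetector import run_detector, sample_points
from .grids import Grid, RasterStack, align, write_grid
from .synthetic import Scene, SceneConfig, make_scene
from .trends import coverage_map, pixel_slope, proportion_trend, trend_map

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every default lands in the manifest."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    compositing_mode: str = "monthly_max_mean"
    alpha: float = 0.05
    two_sided: bool = False
    min_years: int = 5
    k_classes: int = 5
    n_points: int = 1678
    n_perm: int = 299
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = d.pop("scene", {})
        if isinstance(scene, dict):
            if "shape" in scene:
                scene["shape"] = tuple(scene["shape"])
            if "years" in scene:
                scene["years"] = tuple(scene["years"])
            if "gradient" in scene:
                scene["gradient"] = tuple(scene["gradient"])
            if "driver_shape" in scene:
                scene["driver_shape"] = tuple(scene["driver_shape"])
            scene = SceneConfig(**scene)
        return cls(scene=scene, **d)


def _annual_fields(scene: Scene, mode: str) -> RasterStack:
    """Reduce the sub-monthly composites to annual growing-season fields."""
    cfg = CompositeConfig(mode=mode)
    years = sorted({y for (y, m, h) in scene.submonthly_index})
    annual = []
    for year in years:
        monthly = []
        months = []
        for month in cfg.season_months:
            idx = [i for i, (y, m, h) in enumerate(scene.submonthly_index)
                   if y == year and m == month]
            monthly.append(mvc(RasterStack([scene.submonthly[i] for i in idx])))
            months.append(month)
        annual.append(growing_season_ndvi(RasterStack(monthly, time_index=months), cfg))
    return RasterStack(annual, time_index=years)


def _subset(stack: RasterStack, years: np.ndarray) -> RasterStack:
    keep = [i for i, y in enumerate(stack.time_index) if y in set(int(v) for v in years)]
    return RasterStack([stack[i] for i in keep], time_index=[stack.time_index[i] for i in keep])


def run_all(config: RunConfig | None = None, out_dir=None) -> dict:
    """Execute every stage on a synthetic scene and return the report bundle.

    When ``out_dir`` is given, all artifacts (CSV series, GeoTIFF maps,
    JSON manifest) are written beneath it.
    """
    config = config or RunConfig()
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    manifest: dict = {
        "version": __version__,
        "config": {**asdict(config), "scene": asdict(config.scene)},
        "stages": {},
    }

    # 1. simulate
    scene = make_scene(config.scene)
    manifest["stages"]["simulate"] = {
        "n_submonthly": len(scene.submonthly),
        "n_years": config.scene.n_years,
    }
    log.append(f"simulate: {len(scene.submonthly)} sub-monthly composites")

    # 2. composite
    annual = _annual_fields(scene, config.compositing_mode)
    years = np.array(annual.time_index)
    series = AnnualSeries(years, np.array([regional_mean(g) for g in annual]))
    manifest["stages"]["composite"] = {
        "mode": config.compositing_mode,
        "regional_mean_first": series.values[0],
        "regional_mean_last": series.values[-1],
    }
    log.append(f"composite: {len(annual)} annual fields, mode={config.compositing_mode}")

    # 3. change point
    cp = analyze(series, alpha=config.alpha, two_sided=config.two_sided)
    manifest["stages"]["changepoint"] = {
        "split_year": cp.split_year,
        "tau_star": cp.tau_star,
        "t_stat": cp.t_stat,
        "critical": cp.critical,
        "significant": cp.significant,
        "no_change_point": cp.no_change_point,
        "ties": len(cp.tied_taus),
    }
    log.append(f"changepoint: split_year={cp.split_year} |T|={cp.t_stat}")

    # 4. segmented trend + coverage
    if cp.no_change_point:
        raise RuntimeError("changepoint stage found no change point; "
                           "segmented stages cannot proceed")
    seg1, seg2 = segment(series, cp.split_year)
    periods = {
        f"{seg1.years[0]}-{seg1.years[-1]}": seg1.years,
        f"{seg2.years[0]}-{seg2.years[-1]}": seg2.years,
    }
    trend_block = {}
    tmaps = {}
    for label, yrs in periods.items():
        tm = trend_map(_subset(annual, yrs))
        tmaps[label] = tm
        trend_block[label] = {
            "mean_slope": float(tm.slope.values[tm.slope.valid].mean()),
            "class_fractions": tm.class_table.round(6).to_dict(),
            "masked_cells": int(tm.slope.mask.sum()),
        }
    cov_props = {}
    for year, g in zip(annual.time_index, annual):
        cov_props[int(year)] = coverage_map(g).proportions
    cov_df = pd.DataFrame(cov_props).T.sort_index()
    cov_rates = proportion_trend(cov_df)
    manifest["stages"]["trend"] = {
        "periods": trend_block,
        "coverage_rate_percent_per_year": cov_rates.round(6).to_dict(),
    }
    log.append("trend: per-segment slope maps + coverage proportions")

    # 5. correlation per driver and period
    corr_block = {}
    ref = annual.geometry
    aligned_drivers = {
        name: RasterStack([align(g, ref, "bilinear") for g in stack],
                          time_index=list(stack.time_index))
        for name, stack in scene.drivers.items()
    }
    for name, stack in aligned_drivers.items():
        corr_block[name] = {}
        for label, yrs in periods.items():
            cm = correlation_map(_subset(stack, yrs), _subset(annual, yrs),
                                 min_years=config.min_years, name=name)
            pos, neg = sign_fractions(cm)
            corr_block[name][label] = {
                "pct_positive": round(100 * pos, 4),
                "pct_negative": round(100 * neg, 4),
                "mean_r": float(cm.r.values[cm.r.valid].mean()),
                "masked_cells": int(cm.r.mask.sum()),
            }
    manifest["stages"]["correlate"] = corr_block
    log.append(f"correlate: {len(corr_block)} drivers x {len(periods)} periods")

    # 6. geodetector on the annual-mean NDVI
    mean_ndvi_vals = annual.as_array().mean(axis=0)
    mean_ndvi = ref.copy_with(mean_ndvi_vals.filled(ref.nodata),
                              np.ma.getmaskarray(mean_ndvi_vals))
    factor_grids = {}
    for name, stack in aligned_drivers.items():
        arr = stack.as_array().mean(axis=0)
        factor_grids[name] = ref.copy_with(arr.filled(ref.nodata), np.ma.getmaskarray(arr))
    for name, g in scene.static_factors.items():
        method = "nearest" if name in scene.categorical else "bilinear"
        factor_grids[name] = align(g, ref, method)
    table = sample_points(mean_ndvi, factor_grids, n=config.n_points,
                          seed=config.seed, categorical=scene.categorical)
    det = run_detector(table, k_classes=config.k_classes, n_perm=config.n_perm,
                       seed=config.seed)
    manifest["stages"]["detect"] = {
        "n_points": len(table),
        "n_dropped": table.n_dropped,
        **det.to_dict(),
    }
    log.append(f"detect: {len(table)} points ({table.n_dropped} dropped)")

    manifest["log"] = log
    manifest["complete_stages"] = list(manifest["stages"])

    if out:
        pd.DataFrame({"year": series.years, "ndvi": series.values}).to_csv(
            out / "regional_series.csv", index=False)
        with open(out / "changepoint.json", "w") as fh:
            json.dump(cp.to_dict(), fh, indent=1)
        for label, tm in tmaps.items():
            write_grid(tm.slope, out / f"slope_{label}.tif")
            write_grid(tm.class_map, out / f"trend_class_{label}.tif")
        cov_df.to_csv(out / "coverage_proportions.csv")
        det.interaction_q.to_csv(out / "interaction_q.csv")
        det.interaction_class.to_csv(out / "interaction_class.csv")
        table.data.to_csv(out / "sample_table.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
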