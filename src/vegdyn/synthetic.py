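"""Synthetic raster scenes for exercising the full pipeline.

The generator emulates the statistical frame of an alpine headwater
region: a NW-to-SE increasing base-NDVI gradient, an annual regional NDVI
series with a mild decline before a designed change-point year and a
strong rise (plus a level jump in the segment means) after it, two
sub-monthly composites per growing-season month whose nonnegative
"atmospheric" deficits make maximum-value compositing exact, and driver /
static factor fields whose spatial stratification explains a designed
share of the NDVI variance.  Drivers are generated on a coarser grid than
the NDVI so the alignment path is exercised end to end.

Everything is seeded: identical seeds give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import AnnualSeries
from .grids import GeoTransform, Grid, RasterStack

__all__ = [
    "SceneConfig",
    "QDesign",
    "Scene",
    "make_scene",
    "make_stratified_response",
    "make_toy_series",
    "make_step_series",
]

# additive seasonal NDVI offsets per growing-season month (zero mean, so
# the mean of monthly maxima reproduces the annual value); July peak
SEASON_OFFSETS = {5: -0.06, 6: 0.02, 7: 0.06, 8: 0.03, 9: -0.05}


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for the synthetic scene.

    Defaults mirror the frame of the emulated study: 39 annual fields
    (1982-2020), change point after 2009, slight pre-split decline and a
    clearly stronger post-split rise with a level jump between the
    segment means, regional NDVI in the 0.62-0.67 window, and a base
    NDVI rising from the NW to the SE corner.
    """

    shape: tuple[int, int] = (50, 50)
    years: tuple[int, int] = (1982, 2020)
    split_year: int = 2009
    slope_before: float = -0.0004   # NDVI / year within segment 1
    slope_after: float = 0.0018     # NDVI / year within segment 2
    mean_jump: float = 0.04         # segment-2 mean minus segment-1 mean
    base_level: float = 0.625       # regional mean NDVI of segment 1
    gradient: tuple[float, float] = (0.50, 0.75)  # NW corner .. SE corner
    noise_sd: float = 0.005         # interannual (regional) noise
    cell_noise_sd: float = 0.02     # independent per cell-year noise
    deficit_sd: float = 0.04        # sub-monthly atmospheric deficit scale
    driver_shape: tuple[int, int] = (25, 25)  # coarser driver geometry
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if not y0 < self.split_year < y1:
            raise ValueError("split_year must lie strictly inside the year span")
        if self.noise_sd < 0 or self.cell_noise_sd < 0 or self.deficit_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if not (0 < self.gradient[0] < 1 and 0 < self.gradient[1] < 1):
            raise ValueError("base NDVI gradient must lie inside (0, 1)")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


@dataclass(frozen=True)
class QDesign:
    """Design for a stratified response with a target q."""

    strata: np.ndarray
    target_q: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_q < 1.0:
            raise ValueError("target_q must lie in [0, 1); q = 1 needs zero "
                             "within-stratum noise, request target_q -> 1 instead")
        labels = np.asarray(self.strata)
        object.__setattr__(self, "strata", labels)
        if self.target_q > 0 and len(np.unique(labels)) < 2:
            raise ValueError("need >= 2 occupied strata for target_q > 0")


@dataclass
class Scene:
    """Bundle returned by :func:`make_scene`."""

    config: SceneConfig
    submonthly: RasterStack            # (year, month, half) composites
    submonthly_index: list[tuple[int, int, int]]
    annual_true: RasterStack           # noise-free-of-deficit annual fields
    year_effects: np.ndarray
    drivers: dict[str, RasterStack]    # annual driver stacks, coarse geometry
    static_factors: dict[str, Grid]    # coarse geometry
    categorical: tuple[str, ...]

    def regional_series(self) -> AnnualSeries:
        years = np.arange(self.config.years[0], self.config.years[1] + 1)
        vals = [g.values[g.valid].mean() for g in self.annual_true]
        return AnnualSeries(years, np.array(vals))


def _diagonal_field(shape: tuple[int, int]) -> np.ndarray:
    """0 at the NW corner rising to 1 at the SE corner."""
    r, c = shape
    rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    return (rr + cc) / float((r - 1) + (c - 1))


def year_effects(config: SceneConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Regional NDVI anomaly per year: two mean-anchored trend segments.

    Segment 1 carries ``slope_before`` around a zero segment mean;
    segment 2 carries ``slope_after`` around a mean of ``mean_jump``.
    Optional interannual noise (sd ``noise_sd``) is added when a generator
    is supplied.
    """
    y0, y1 = config.years
    n1 = config.split_year - y0 + 1
    n2 = y1 - config.split_year
    t1 = np.arange(n1) - (n1 - 1) / 2.0
    t2 = np.arange(n2) - (n2 - 1) / 2.0
    e = np.concatenate([config.slope_before * t1,
                        config.mean_jump + config.slope_after * t2])
    if rng is not None and config.noise_sd > 0:
        e = e + rng.normal(0.0, config.noise_sd, len(e))
    return e


def _geometry(shape: tuple[int, int]) -> GeoTransform:
    # a 0.1-degree-per-cell window anchored like the emulated region
    return GeoTransform(x0=96.0, y0=36.0, dx=4.0 / shape[1], dy=-4.0 / shape[0])


def make_scene(config: SceneConfig | None = None) -> Scene:
    """Generate the full synthetic input suite for one run."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    gt = _geometry(config.shape)
    gt_drv = _geometry(config.driver_shape)

    diag = _diagonal_field(config.shape)
    g0, g1 = config.gradient
    base = g0 + (g1 - g0) * diag
    base = base - base.mean() + config.base_level  # pin the regional mean

    eff = year_effects(config, rng)
    years = np.arange(config.years[0], config.years[1] + 1)

    annual_grids, sub_grids, sub_index = [], [], []
    for yi, year in enumerate(years):
        annual = base + eff[yi]
        if config.cell_noise_sd > 0:
            annual = annual + rng.normal(0.0, config.cell_noise_sd, (rows, cols))
        annual = np.clip(annual, -0.29, 1.0)
        annual_grids.append(Grid(annual, gt))
        for month in sorted(SEASON_OFFSETS):
            monthly = np.clip(annual + SEASON_OFFSETS[month], -0.29, 1.0)
            d1 = np.abs(rng.normal(0.0, config.deficit_sd, (rows, cols)))
            d2 = np.abs(rng.normal(0.0, config.deficit_sd, (rows, cols)))
            lo = np.minimum(d1, d2)
            d1, d2 = d1 - lo, d2 - lo  # one composite per month is deficit-free
            for half, d in enumerate((d1, d2), start=1):
                sub_grids.append(Grid(np.clip(monthly - d, -0.3, 1.0), gt))
                sub_index.append((int(year), month, half))

    submonthly = RasterStack(sub_grids, time_index=list(range(len(sub_grids))))
    annual_true = RasterStack(annual_grids, time_index=[int(y) for y in years])

    diag_d = _diagonal_field(config.driver_shape)
    dr, dc = config.driver_shape

    def noisy(base_field: np.ndarray, sd: float) -> np.ndarray:
        return base_field + rng.normal(0.0, sd, (dr, dc))

    # annual drivers: spatial base + a response to the NDVI year effect
    driver_design = {
        # name: (base field, annual coupling to the year effect, annual noise sd)
        "precipitation": (480.0 + 660.0 * noisy(diag_d, 0.02), 2000.0, 15.0),
        "temperature": (-8.0 + 12.0 * noisy(np.tile(np.linspace(0, 1, dc), (dr, 1)), 0.05),
                        20.0, 0.3),
        "soil_moisture": (0.30 + 0.35 * noisy(diag_d, 0.15), 0.8, 0.02),
        "soil_temperature": (-6.0 + 11.0 * noisy(diag_d, 0.08), 15.0, 0.4),
        "evapotranspiration": (230.0 + 400.0 * noisy(np.tile(np.linspace(0, 1, dc), (dr, 1)), 0.10),
                               800.0, 12.0),
    }
    drivers = {}
    for name, (base_f, coupling, sd) in driver_design.items():
        grids = []
        for yi, year in enumerate(years):
            f = base_f + coupling * eff[yi] + rng.normal(0.0, sd, (dr, dc))
            grids.append(Grid(f, gt_drv))
        drivers[name] = RasterStack(grids, time_index=[int(y) for y in years])

    elevation = 6200.0 - 3700.0 * noisy(diag_d, 0.12)
    slope_deg = np.abs(rng.normal(8.0, 6.0, (dr, dc)))
    aspect = rng.integers(0, 9, (dr, dc)).astype(float)  # 0 flat, 1..8 sectors
    land_use = rng.integers(1, 5, (dr, dc)).astype(float)  # patches uncorrelated with NDVI
    gdp = np.exp(rng.normal(0.0, 1.0, (dr, dc)))
    population = np.exp(rng.normal(1.0, 1.0, (dr, dc)))
    static = {
        "elevation": Grid(elevation, gt_drv),
        "slope": Grid(slope_deg, gt_drv),
        "aspect": Grid(aspect, gt_drv),
        "land_use": Grid(land_use, gt_drv),
        "gdp": Grid(gdp, gt_drv),
        "population_density": Grid(population, gt_drv),
    }
    return Scene(
        config=config,
        submonthly=submonthly,
        submonthly_index=sub_index,
        annual_true=annual_true,
        year_effects=eff,
        drivers=drivers,
        static_factors=static,
        categorical=("aspect", "land_use"),
    )


def make_stratified_response(design: QDesign) -> np.ndarray:
    """Response whose stratification explains a designed variance share.

    Stratum means are equally spaced and standardized (weighted by
    occupancy) to a population variance of exactly ``target_q``; within-
    stratum Gaussian noise carries the remaining ``1 - target_q``, so the
    sample q converges to the target as n grows.
    """
    labels = np.asarray(design.strata)
    uniq, codes = np.unique(labels, return_inverse=True)
    L = len(uniq)
    n = len(labels)
    rng = np.random.default_rng(design.seed)
    sigma_b2 = design.target_q
    sigma_w2 = 1.0 - design.target_q
    if sigma_b2 == 0.0 or L == 1:
        means = np.zeros(L)
    else:
        raw = np.linspace(-1.0, 1.0, L)
        w = np.bincount(codes, minlength=L) / n
        mu = (w * raw).sum()
        var = (w * (raw - mu) ** 2).sum()
        means = (raw - mu) * np.sqrt(sigma_b2 / var)
    y = means[codes]
    if sigma_w2 > 0:
        y = y + rng.normal(0.0, np.sqrt(sigma_w2), n)
    return y


def make_toy_series(kind: str, n: int, **params) -> AnnualSeries:
    """Deterministic canonical series (step / ramp / constant) for oracles."""
    if n < 4:
        raise ValueError("n must be >= 4")
    years = np.arange(params.get("start_year", 1), params.get("start_year", 1) + n)
    if kind == "step":
        levels = params.get("levels", (0.0, 10.0))
        tau = params.get("tau", n // 2)
        vals = np.where(np.arange(n) < tau, levels[0], levels[1]).astype(float)
    elif kind == "ramp":
        vals = np.arange(1, n + 1, dtype=float)
    elif kind == "constant":
        vals = np.full(n, float(params.get("level", 0.0)))
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    return AnnualSeries(years, vals)


def make_step_series(n: int, tau0: int, shift_sd: float = 3.0, noise_sd: float = 1.0,
                     seed: int = 0) -> AnnualSeries:
    """Noisy step series for change-point recovery studies.

    The mean shift is ``shift_sd`` within-segment standard deviations
    (3 by default, comfortably above the ~2-sigma identifiability floor
    for a +/-1-year locate at n around 40).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, n)
    x[tau0:] += shift_sd * noise_sd
    return AnnualSeries(np.arange(1, n + 1), x)
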