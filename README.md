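# vegdyn

Vegetation-dynamics analysis for raster NDVI time series: growing-season
compositing, change-point detection, per-pixel trend and coverage
classification, NDVI–driver correlation mapping, and Geodetector
factor/interaction attribution — as one tested, scriptable pipeline.

The package targets the workflow used in regional vegetation-monitoring
studies of arid and alpine basins: a multi-decade stack of sub-monthly
NDVI composites (e.g. AVHRR GIMMS NDVI3g, 15-day, 0.083°) is reduced to
annual May–September growing-season fields, the regional mean series is
tested for a regime shift, and the periods before and after the shift are
characterized spatially (trends, coverage classes, correlations with
climate drivers) and attributed (which drivers explain the spatial
pattern of NDVI, alone and in interaction). A seeded synthetic scene
generator reproduces the statistical structure of such a study — a
NW→SE greenness gradient, a mild decline followed by a strong rise with
a known change-point year, coupled driver fields — so every stage runs
and is tested without any data download.

## Methods at a glance

* **Maximum-value compositing (MVC).** Per-cell maximum over each month's
  sub-monthly composites, suppressing cloud/atmosphere-depressed values;
  the May–September monthly maxima are then averaged (or max-reduced) to
  one annual field.
* **Ordered cluster analysis (OCA).** For every admissible split τ of the
  annual regional series x₁…xₙ, S_n(τ) = V_τ + V_{n−τ} with
  V_τ = Σ_{t≤τ}(x_t − x̄_τ)² and V_{n−τ} = Σ_{t>τ}(x_t − x̄_{n−τ})²;
  the change point τ\* minimizes S_n. The mean jump is tested with a
  pooled two-sample statistic |T| against the normal quantile at 1−α
  (1.64 at α = 0.05; a strict two-sided option is available).
* **Trend mapping.** Per-pixel OLS slope θ_slope of NDVI on the year
  index, binned into five classes from obvious degradation
  (θ ≤ −0.0019) to significant improvement (θ ≥ 0.0006); annual NDVI is
  binned into six coverage classes on (−0.3, 1].
* **Correlation mapping.** Per-pixel Pearson r between annual NDVI and
  each driver per period, with positive/negative area shares.
* **Geodetector.** Factors are discretized by Jenks natural breaks
  (Fisher's optimal partition); the factor detector computes
  q = 1 − Σ_h N_h σ_h² / (N σ²), the share of spatial NDVI variance a
  stratification explains; the interaction detector computes q on the
  overlay of two factors and classifies each pair (enhancement /
  weakening / independence). Significance is a seeded permutation test
  (noncentral-F reference optional).

## Worked example

```python
from vegdyn.pipeline import RunConfig, run_all

manifest = run_all(RunConfig())          # default synthetic scene, seeded
cp = manifest["stages"]["changepoint"]
print(cp["split_year"], cp["t_stat"], cp["significant"])
```

prints, for the default scene (50×50 cells, 1982–2020, designed change
point after 2009):

```
split_year=2009  |T|=18.50  critical=1.64  significant=True
1982-2009: mean slope -0.000420 NDVI/yr
2010-2020: mean slope +0.002190 NDVI/yr
q(precipitation) = 0.93***
q(soil_temperature) = 0.89***
q(elevation) = 0.82***
precipitation r>0 share, 2010-2020: 84.03%
```

The change point is found exactly at the designed year and the jump in
segment means is highly significant; the pre-split regional trend is
slightly negative and the post-split trend strongly positive, matching
the designed regimes; precipitation — the driver built to share the NDVI
gradient most closely — ranks first in explanatory power, with stars per
the permutation test (\*\*\* : p < 0.01).

The same stages are available from the shell:

```bash
vegdyn run-all --out runs/demo --seed 1
vegdyn simulate --out runs/sim --seed 1
vegdyn changepoint runs/sim/regional_series.csv --out runs/cp.json
```

Each run writes a JSON manifest (full config echo, seeds, per-stage
counts of masked cells and dropped points), CSV series/tables, and
GeoTIFF maps; reruns with the same config are byte-identical.

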