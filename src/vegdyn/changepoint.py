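"""Ordered cluster analysis (OCA) for a single change point in an annual series.

The series is split at every admissible year index tau; for each split the
within-segment sums of squared deviations

    V_tau      = sum_{t<=tau} (x_t - mean of first segment)^2
    V_{n-tau}  = sum_{t>tau}  (x_t - mean of second segment)^2
    S_n(tau)   = V_tau + V_{n-tau}

are accumulated, and the optimal split tau* minimizes S_n.  A pooled
two-sample t statistic |T| then tests whether the segment means differ;
the threshold is the standard-normal quantile at 1 - alpha by default
(1.64 at alpha = 0.05), with a strict two-sided option.

The scan range is 2 <= tau <= n-2 so both segments always hold at least
two points and the jump test is defined at tau*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AnnualSeries",
    "ChangePointResult",
    "segment_deviations",
    "oca_scan",
    "jump_test",
    "critical_value",
    "segment",
]

# a local S_n minimum is reported as a secondary valley if it sits within
# this fraction of S_n(tau*) above the global minimum (diagnostic only)
SECONDARY_MINIMA_PROMINENCE = 0.10

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class AnnualSeries:
    """Gap-free annual series (years strictly increasing, consecutive)."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or years.shape != values.shape:
            raise ValueError("years and values must be 1-D and equal-length")
        if len(years) < 1:
            raise ValueError("series is empty")
        d = np.diff(years)
        if np.any(d <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(d != 1):
            raise ValueError("series has gaps; fill or trim before analysis")
        if not np.all(np.isfinite(values)):
            raise ValueError("series contains non-finite values")

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class ChangePointResult:
    """Full outcome of an ordered-cluster scan and jump test."""

    taus: np.ndarray
    sn_curve: np.ndarray
    tau_star: int | None
    split_year: int | None
    mean_before: float | None
    mean_after: float | None
    v_before: float | None
    v_after: float | None
    t_stat: float | None = None
    critical: float | None = None
    significant: bool | None = None
    no_change_point: bool = False
    tied_taus: list[int] = field(default_factory=list)
    secondary_minima: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "taus": self.taus.tolist(),
            "sn_curve": self.sn_curve.tolist(),
            "tau_star": self.tau_star,
            "split_year": self.split_year,
            "mean_before": self.mean_before,
            "mean_after": self.mean_after,
            "v_before": self.v_before,
            "v_after": self.v_after,
            "t_stat": self.t_stat,
            "critical": self.critical,
            "significant": self.significant,
            "no_change_point": self.no_change_point,
            "tied_taus": self.tied_taus,
            "secondary_minima": self.secondary_minima,
        }


def segment_deviations(series: AnnualSeries, tau: int) -> tuple[float, float, float]:
    """(V_tau, V_{n-tau}, S_n) for a split after the tau-th point (1-based)."""
    n = len(series)
    if not 1 <= tau <= n - 1:
        raise ValueError(f"tau={tau} out of range 1..{n - 1}")
    x = series.values
    a, b = x[:tau], x[tau:]
    v1 = float(((a - a.mean()) ** 2).sum())
    v2 = float(((b - b.mean()) ** 2).sum())
    return v1, v2, v1 + v2


def _sn_all(x: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """S_n(tau) for all candidates via prefix sums (O(n))."""
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    t = taus.astype(np.float64)
    n = len(x)
    s1a, s2a = c1[taus - 1], c2[taus - 1]
    v1 = s2a - s1a**2 / t
    s1b, s2b = c1[-1] - s1a, c2[-1] - s2a
    v2 = s2b - s1b**2 / (n - t)
    return np.maximum(v1, 0.0) + np.maximum(v2, 0.0)


def oca_scan(series: AnnualSeries) -> ChangePointResult:
    """Scan all admissible splits and return the S_n-minimizing one.

    A flat curve (constant series) yields ``no_change_point=True``; exact
    ties at the minimum resolve to the earliest tau and are recorded.
    """
    n = len(series)
    if n < 4:
        raise ValueError("need n >= 4 so both segments can hold >= 2 points")
    x = series.values
    taus = np.arange(2, n - 1)
    sn = _sn_all(x, taus)

    smin = sn.min()
    tie_mask = sn <= smin + _TIE_EPS * max(1.0, abs(smin))
    tied = taus[tie_mask].tolist()
    scale = float(np.abs(x).max())
    constant = bool(np.all(np.abs(x - x[0]) <= _TIE_EPS * max(1.0, scale)))
    if constant:
        return ChangePointResult(
            taus=taus, sn_curve=sn, tau_star=None, split_year=None,
            mean_before=None, mean_after=None, v_before=None, v_after=None,
            no_change_point=True, tied_taus=tied,
        )
    tau_star = tied[0]
    v1, v2, _ = segment_deviations(series, tau_star)

    interior = np.arange(1, len(taus) - 1)
    local_min = interior[(sn[interior] < sn[interior - 1]) & (sn[interior] < sn[interior + 1])]
    cutoff = smin + SECONDARY_MINIMA_PROMINENCE * max(smin, _TIE_EPS)
    secondary = [int(taus[i]) for i in local_min if taus[i] != tau_star and sn[i] <= cutoff]

    return ChangePointResult(
        taus=taus, sn_curve=sn,
        tau_star=int(tau_star),
        split_year=int(series.years[tau_star - 1]),
        mean_before=float(x[:tau_star].mean()),
        mean_after=float(x[tau_star:].mean()),
        v_before=v1, v_after=v2,
        tied_taus=tied if len(tied) > 1 else [],
        secondary_minima=secondary,
    )


def critical_value(alpha: float, two_sided: bool = False) -> float:
    """Threshold for |T|: the standard-normal quantile at 1 - alpha.

    The default one-tail convention prints 1.64 at alpha = 0.05;
    ``two_sided=True`` gives the strict two-sided quantile (1.96).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    return float(stats.norm.ppf(q))


def jump_test(
    series: AnnualSeries, tau: int, alpha: float = 0.05, two_sided: bool = False
) -> tuple[float, float, bool]:
    """Pooled two-sample t statistic for the mean jump at ``tau``.

    |T| = |mean1 - mean2| / (s_p * sqrt(1/tau + 1/(n-tau))) with s_p the
    pooled within-segment standard deviation.  Degenerate zero-variance
    segments give |T| = inf (unequal means) or 0 (equal means).
    """
    n = len(series)
    if not 2 <= tau <= n - 2:
        raise ValueError("both segments need >= 2 points for the jump test")
    v1, v2, _ = segment_deviations(series, tau)
    x = series.values
    m1, m2 = x[:tau].mean(), x[tau:].mean()
    crit = critical_value(alpha, two_sided)
    sp2 = (v1 + v2) / (n - 2)
    if sp2 == 0.0:
        t = 0.0 if m1 == m2 else float("inf")
    else:
        t = abs(m1 - m2) / (np.sqrt(sp2) * np.sqrt(1.0 / tau + 1.0 / (n - tau)))
    return float(t), crit, bool(t > crit)


def analyze(series: AnnualSeries, alpha: float = 0.05, two_sided: bool = False) -> ChangePointResult:
    """oca_scan plus the jump test at the detected split."""
    res = oca_scan(series)
    if not res.no_change_point:
        t, crit, sig = jump_test(series, res.tau_star, alpha, two_sided)
        res.t_stat, res.critical, res.significant = t, crit, sig
    return res


def segment(series: AnnualSeries, split_year: int) -> tuple[AnnualSeries, AnnualSeries]:
    """Split into (..., split_year) inclusive and (split_year+1, ...)."""
    years = series.years
    if split_year < years[0] + 1 or split_year > years[-1] - 1:
        raise ValueError(f"split year {split_year} must lie strictly inside "
                         f"{years[0]}..{years[-1]}")
    k = int(np.searchsorted(years, split_year)) + 1
    return (
        AnnualSeries(years[:k], series.values[:k]),
        AnnualSeries(years[k:], series.values[k:]),
    )
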