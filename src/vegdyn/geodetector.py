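"""Geodetector: spatial stratified-heterogeneity attribution.

The factor detector measures how much of a response's spatial variance a
categorical stratification explains:

    q = 1 - sum_h N_h * var_h / (N * var) = 1 - SSW / SST

with population (divide-by-count) variances in both numerator and
denominator, so q is exactly the between-strata share of the total sum of
squares and lies in [0, 1].  The interaction detector computes q on the
Cartesian overlay of two factors' strata and classifies the result against
the single-factor q values (weakening / enhancement taxonomy).  Because
the overlay refines both partitions, on the same sample q(A.B) can never
fall below max(q(A), q(B)) beyond rounding — "enhancement" is the
structural outcome.

Continuous factors are discretized with Jenks natural breaks (Fisher's
optimal contiguous partition); significance comes from a seeded
permutation test by default, with the noncentral-F reference distribution
of the original Geodetector software available for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid

__all__ = [
    "SampleTable",
    "DetectorResult",
    "jenks_breaks",
    "stratify",
    "sample_points",
    "factor_q",
    "q_significance",
    "interaction_q",
    "classify_interaction",
    "run_detector",
    "significance_stars",
]

INDEPENDENCE_EPS = 1e-6
DEFAULT_K_CLASSES = 5
DEFAULT_N_PERM = 999
MIN_POINTS = 30

INTERACTION_CATEGORIES = (
    "independence",
    "nonlinear enhancement",
    "double-factor enhancement",
    "nonlinear weakening",
    "single-factor nonlinear weakening",
)


@dataclass
class SampleTable:
    """Sampled points with response and per-factor values.

    ``data`` holds columns ``point_id, x, y, response`` plus one column
    per factor; ``categorical`` names the factors whose values are already
    class labels and must bypass discretization (land use, aspect
    sectors).  Points carrying any masked layer value were dropped at
    sampling time; ``n_dropped`` records how many.
    """

    data: pd.DataFrame
    categorical: tuple[str, ...] = ()
    n_dropped: int = 0

    @property
    def factors(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("point_id", "x", "y", "response")]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DetectorResult:
    q_by_factor: pd.Series
    p_by_factor: pd.Series
    interaction_q: pd.DataFrame
    interaction_class: pd.DataFrame
    n_used: int
    stars: pd.Series = field(default_factory=pd.Series)

    def to_dict(self) -> dict:
        return {
            "q_by_factor": self.q_by_factor.round(12).to_dict(),
            "p_by_factor": self.p_by_factor.round(12).to_dict(),
            "stars": self.stars.to_dict(),
            "interaction_q": {
                a: {b: (None if pd.isna(v) else round(float(v), 12))
                    for b, v in row.items()}
                for a, row in self.interaction_q.iterrows()
            },
            "interaction_class": {
                a: {b: (None if pd.isna(v) else v) for b, v in row.items()}
                for a, row in self.interaction_class.iterrows()
            },
            "n_used": self.n_used,
        }


def jenks_breaks(values, k: int) -> np.ndarray:
    """Natural-breaks thresholds: the optimal contiguous k-partition.

    Dynamic program over the sorted values minimizing total within-class
    sum of squared deviations (Fisher's algorithm, O(k n^2)).  Returns the
    k-1 thresholds as the smallest member of each upper class, so that
    :func:`stratify`'s "equal goes up" rule reproduces the partition.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(x)) < k:
        raise ValueError(f"k={k} exceeds the {len(np.unique(x))} distinct values")
    if k == 1:
        return np.empty(0)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    idx = np.arange(n + 1)
    for m in range(1, k + 1):
        # candidate last-class starts i for every end j, vectorized over i
        for j in range(m, n + 1):
            i = idx[m - 1 : j]
            s = c1[j] - c1[i]
            ss = c2[j] - c2[i] - s * s / (j - i)
            tot = cost[m - 1, i] + ss
            a = int(np.argmin(tot))  # earliest index wins exact ties
            cost[m, j], back[m, j] = tot[a], i[a]
    cuts = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        if m > 1:
            cuts.append(x[i])
        j = i
    return np.array(sorted(cuts))


def stratify(values, thresholds) -> np.ndarray:
    """Stratum labels 1..L from sorted thresholds (left-closed bins).

    A value equal to a threshold joins the upper stratum.
    """
    t = np.asarray(thresholds, dtype=np.float64)
    if np.any(np.diff(t) < 0):
        raise ValueError("thresholds must be sorted")
    return np.searchsorted(t, np.asarray(values, dtype=np.float64), side="right") + 1


def sample_points(response: Grid, factor_grids: dict[str, Grid], n: int, seed: int,
                  categorical: tuple[str, ...] = ()) -> SampleTable:
    """Draw n distinct random cells and extract all co-registered layers.

    Points falling on a masked cell in the response or any factor are
    dropped (the outlier-removal step); if fewer than 30 survive the table
    is refused.
    """
    if n < MIN_POINTS:
        raise ValueError(f"n must be >= {MIN_POINTS}")
    for name, g in factor_grids.items():
        if not g.same_geometry(response):
            raise ValueError(f"factor {name!r} is not co-registered with the response")
    rows, cols = response.shape
    n_cells = rows * cols
    if n > n_cells:
        raise ValueError(f"n={n} exceeds the {n_cells} cells of the grid")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n, replace=False)
    rr, cc = np.unravel_index(flat, (rows, cols))
    keep = response.valid[rr, cc]
    for g in factor_grids.values():
        keep &= g.valid[rr, cc]
    n_dropped = int(n - keep.sum())
    rr, cc = rr[keep], cc[keep]
    if len(rr) < MIN_POINTS:
        raise ValueError(
            f"only {len(rr)} points remain after dropping {n_dropped}; need >= {MIN_POINTS}"
        )
    x, y = response.transform.cell_center(rr, cc)
    data = {"point_id": np.arange(len(rr)), "x": x, "y": y,
            "response": response.values[rr, cc]}
    for name, g in factor_grids.items():
        data[name] = g.values[rr, cc]
    return SampleTable(pd.DataFrame(data), categorical=tuple(categorical),
                       n_dropped=n_dropped)


def _sums_by_stratum(y: np.ndarray, codes: np.ndarray, L: int):
    n_h = np.bincount(codes, minlength=L)
    s_h = np.bincount(codes, weights=y, minlength=L)
    s2_h = np.bincount(codes, weights=y * y, minlength=L)
    return n_h, s_h, s2_h


def factor_q(y, strata) -> float:
    """q = 1 - SSW/SST of the response under a stratification."""
    y = np.asarray(y, dtype=np.float64)
    labels = np.asarray(strata)
    if len(y) != len(labels):
        raise ValueError("y and strata must be equal length")
    if len(y) < 2:
        raise ValueError("need at least two points")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("q undefined: response has zero total variance")
    _, codes = np.unique(labels, return_inverse=True)
    n_h, s_h, s2_h = _sums_by_stratum(y, codes, codes.max() + 1)
    occupied = n_h > 0
    ssw = float((s2_h[occupied] - s_h[occupied] ** 2 / n_h[occupied]).sum())
    q = 1.0 - ssw / sst
    return float(min(1.0, max(0.0, q)))


def q_significance(y, strata, method: str = "permutation",
                   n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> float:
    """p-value for the observed q.

    permutation (default): share of strata relabelings whose q meets or
    exceeds the observed one, with the +1 correction.  noncentral_f: the
    reference distribution of the original Geodetector software,
    F = (N-L)/(L-1) * q/(1-q) against a noncentral F(L-1, N-L; lambda).
    """
    y = np.asarray(y, dtype=np.float64)
    labels = np.asarray(strata)
    q_obs = factor_q(y, labels)
    if method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        _, codes = np.unique(labels, return_inverse=True)
        L = codes.max() + 1
        sst = float(((y - y.mean()) ** 2).sum())
        hits = 0
        yy = y * y
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            n_h = np.bincount(perm, minlength=L)
            s_h = np.bincount(perm, weights=y, minlength=L)
            s2_h = np.bincount(perm, weights=yy, minlength=L)
            occ = n_h > 0
            ssw = float((s2_h[occ] - s_h[occ] ** 2 / n_h[occ]).sum())
            if 1.0 - ssw / sst >= q_obs - 1e-12:
                hits += 1
        return (1 + hits) / (1 + n_perm)
    if method == "noncentral_f":
        _, codes = np.unique(labels, return_inverse=True)
        L = codes.max() + 1
        N = len(y)
        if q_obs >= 1.0:
            return 0.0
        F = (N - L) / max(L - 1, 1) * q_obs / (1.0 - q_obs)
        n_h, s_h, _ = _sums_by_stratum(y, codes, L)
        mean_h = s_h / np.maximum(n_h, 1)
        sigma2 = float(np.var(y))
        lam = (np.sum(mean_h[n_h > 0] ** 2)
               - np.sum(np.sqrt(n_h[n_h > 0]) * mean_h[n_h > 0]) ** 2 / N) / sigma2
        lam = max(lam, 0.0)
        return float(stats.ncf.sf(F, L - 1, N - L, lam))
    raise ValueError(f"unknown method {method!r}")


def interaction_q(y, strata_a, strata_b) -> float:
    """q of the Cartesian overlay of two stratifications."""
    a = np.asarray(strata_a)
    b = np.asarray(strata_b)
    if len(a) != len(b):
        raise ValueError("strata vectors must be equal length")
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    overlay = ca * (cb.max() + 1) + cb  # occupied pairs only survive np.unique
    return factor_q(y, overlay)


def classify_interaction(q_a: float, q_b: float, q_ab: float,
                         epsilon: float = INDEPENDENCE_EPS) -> str:
    """Five-way interaction taxonomy against the single-factor q values."""
    for v in (q_a, q_b, q_ab):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"q value {v} outside [0, 1]")
    if abs(q_ab - (q_a + q_b)) <= epsilon:
        return "independence"
    if q_ab > q_a + q_b:
        return "nonlinear enhancement"
    if q_ab > max(q_a, q_b):
        return "double-factor enhancement"
    if q_ab < min(q_a, q_b):
        return "nonlinear weakening"
    return "single-factor nonlinear weakening"


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def run_detector(table: SampleTable, k_classes: int | dict[str, int] = DEFAULT_K_CLASSES,
                 n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                 method: str = "permutation") -> DetectorResult:
    """Full factor + interaction detection on a sample table.

    Continuous factors are discretized with Jenks natural breaks (k per
    factor, default 5); factors named in ``table.categorical`` pass
    through unchanged.  Every factor gets q and a p-value; every pair gets
    the overlay q and its taxonomy category.
    """
    y = table.data["response"].to_numpy(dtype=np.float64)
    factors = table.factors
    if not factors:
        raise ValueError("table has no factor columns")
    strata: dict[str, np.ndarray] = {}
    for name in factors:
        vals = table.data[name].to_numpy()
        if name in table.categorical:
            strata[name] = vals
        else:
            k = k_classes.get(name, DEFAULT_K_CLASSES) if isinstance(k_classes, dict) else k_classes
            vals = vals.astype(np.float64)
            k_eff = min(k, len(np.unique(vals)))
            strata[name] = stratify(vals, jenks_breaks(vals, k_eff))

    qs = pd.Series({f: factor_q(y, strata[f]) for f in factors})
    seeds = np.random.SeedSequence(seed).spawn(len(factors))
    ps = pd.Series({
        f: q_significance(y, strata[f], method=method, n_perm=n_perm,
                          seed=int(s.generate_state(1)[0] % (2**31)))
        for f, s in zip(factors, seeds)
    })
    stars = ps.map(significance_stars)

    iq = pd.DataFrame(np.nan, index=factors, columns=factors, dtype=float)
    icls = pd.DataFrame(None, index=factors, columns=factors, dtype=object)
    for i, a in enumerate(factors):
        iq.loc[a, a] = qs[a]
        for b in factors[i + 1:]:
            v = interaction_q(y, strata[a], strata[b])
            iq.loc[a, b] = iq.loc[b, a] = v
            cat = classify_interaction(qs[a], qs[b], v)
            icls.loc[a, b] = icls.loc[b, a] = cat
    return DetectorResult(
        q_by_factor=qs, p_by_factor=ps, interaction_q=iq,
        interaction_class=icls, n_used=len(table), stars=stars,
    )
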