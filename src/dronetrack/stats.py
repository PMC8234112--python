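"""Inferential statistics used by the activity analysis.

Three computations: a Mann-Whitney U comparison of two observation
series (U reported as min(U1, U2)), a chi-square goodness-of-fit on
binned per-drone flight counts, and Pearson correlations of daily flight
numbers against weather.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collectable

    statistic: float
    p_value: float
    n1: Optional[int] = None
    n2: Optional[int] = None
    df: Optional[int] = None
    method: str = ""


def _exact_mwu_p(u_obs: float, n1: int, n2: int) -> float:
    """Two-sided exact p by enumerating all rank assignments (no ties)."""
    n = n1 + n2
    ranks = range(1, n + 1)
    base = n1 * n2 + n1 * (n1 + 1) / 2
    count_le = 0
    for subset in combinations(ranks, n1):
        u1 = base - sum(subset)
        if min(u1, n1 * n2 - u1) <= u_obs + 1e-12:
            count_le += 1
    return min(1.0, count_le / comb(n, n1))


def mann_whitney_u(sample1: Sequence[float], sample2: Sequence[float]) -> TestResult:
    """Mann-Whitney U with U = min(U1, U2).

    U1 = n1*n2 + n1(n1+1)/2 - R1, with R1 the rank sum of sample1 in the
    pooled ranking (mid-ranks for ties).  The p-value is exact (full
    enumeration) for n1, n2 <= 8 without ties, else a tie-corrected
    normal approximation with continuity correction.  All-tied input has
    zero variance and reports p = 1.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = n1 * n2 + n1 * (n1 + 1) / 2.0 - r1
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n1 <= 8 and n2 <= 8:
        p = _exact_mwu_p(u, n1, n2)
        method = "mann-whitney-u/exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(u, 1.0, n1, n2, method="mann-whitney-u/degenerate")
        z = (u - mu + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "mann-whitney-u/normal-tie-corrected"
    return TestResult(u, float(p), n1, n2, method=method)


def chi_square_gof(observed_counts: Sequence[float], expected_counts: Sequence[float]) -> TestResult:
    """Goodness-of-fit chi-square: sum (O-E)^2 / E with df = bins - 1."""
    obs = np.asarray(observed_counts, dtype=float)
    exp = np.asarray(expected_counts, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be equal-length vectors")
    if obs.size < 2:
        raise ValueError("need at least 2 bins")
    if (exp <= 0).any():
        raise ValueError("expected counts must all be positive")
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(statistic, df))
    return TestResult(statistic, p, df=df, method="chi-square-gof")


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> TestResult:
    n = x.size
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(float("nan"), float("nan"), n1=n, method=f"pearson/{label}/undefined-constant-series")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), n1=n, method=f"pearson/{label}")


@dataclass(frozen=True)
class WeatherCorrelation:
    r_temp: TestResult
    r_precip: TestResult
    r_temp_precip: TestResult


def weather_correlation(daily: pd.DataFrame, weather: pd.DataFrame) -> WeatherCorrelation:
    """Pearson r of daily flight numbers vs temperature and precipitation.

    ``daily`` needs columns (date, n_flights); ``weather`` needs
    (date, mean_temp, precipitation).  Frames are inner-joined on date;
    fewer than 3 paired days is an error.  A constant series yields an
    undefined (NaN) correlation, flagged in the method tag.
    """
    merged = pd.merge(
        daily.assign(date=pd.to_datetime(daily["date"]).dt.date),
        weather.assign(date=pd.to_datetime(weather["date"]).dt.date),
        on="date",
        how="inner",
    )
    if len(merged) < 3:
        raise ValueError(f"need at least 3 paired days, got {len(merged)}")
    flights = merged["n_flights"].to_numpy(dtype=float)
    temp = merged["mean_temp"].to_numpy(dtype=float)
    precip = merged["precipitation"].to_numpy(dtype=float)
    return WeatherCorrelation(
        r_temp=_pearson(flights, temp, "flights-vs-temp"),
        r_precip=_pearson(flights, precip, "flights-vs-precip"),
        r_temp_precip=_pearson(temp, precip, "temp-vs-precip"),
    )


def flight_count_gof(
    counts_per_drone: Sequence[int],
    bin_edges: Sequence[float] = (1, 10, 30, 50),
) -> TestResult:
    """Chi-square of binned per-drone flight counts against a uniform null.

    Default bins are 1-9, 10-29, 30-49 flights (df = 2); drones with zero
    flights are excluded, counts past the top edge land in the last bin.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(edges) < 3:
        raise ValueError("bin_edges must be increasing with at least 3 values")
    counts = [c for c in counts_per_drone if c >= edges[0]]
    if not counts:
        raise ValueError("no drones with flights in range")
    observed = np.zeros(len(edges) - 1)
    for c in counts:
        idx = np.searchsorted(edges, c, side="right") - 1
        observed[min(idx, len(observed) - 1)] += 1
    expected = np.full_like(observed, observed.sum() / observed.size)
    return chi_square_gof(observed, expected)
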