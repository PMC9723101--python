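"""Classical statistics used throughout the pipeline.

Pearson correlation with the t-transform p-value, Fisher r-to-z comparison of
two correlation coefficients, Welch's unequal-variance t-test, paired and
one-sample t-tests, ordinary least-squares slope, and normalization of
mutational-signature counts by the clock-like burden (SBS1 + SBS5).

p-values come from the standard t / normal distribution functions; nothing is
multiple-testing corrected here — callers see raw two-sided p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

CLOCK_LIKE = ("SBS1", "SBS5")


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its t-test."""

    r: float
    n: int
    t_stat: float
    p_two_sided: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_two_sided: float
    df: float
    n1: int
    n2: int | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict, compare=False)


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided p from t = r·sqrt((n−2)/(1−r²)), df = n−2."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, n, math.inf if r > 0 else -math.inf, 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r, n, t, float(p))


def compare_correlations_fisher(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test of two correlation coefficients from independent samples.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided normal p.

    Note: when the two correlations share a variable (e.g. r(SNV, age) vs
    r(SNV, SV) on the same tumors) they are dependent and this independent-
    sample test is only an approximation; a dependent-correlation test would
    need the third inter-correlation.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return z, float(p)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    aa, ba = _as_1d(a, "a"), _as_1d(b, "b")
    if len(aa) < 2 or len(ba) < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = aa.var(ddof=1), ba.var(ddof=1)
    if va == 0 and vb == 0:
        if aa.mean() == ba.mean():
            return TTestResult(0.0, 1.0, float("nan"), len(aa), len(ba), degenerate=True)
        sign = 1.0 if aa.mean() > ba.mean() else -1.0
        return TTestResult(sign * math.inf, 0.0, float("nan"), len(aa), len(ba), degenerate=True)
    res = sps.ttest_ind(aa, ba, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df), len(aa), len(ba))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired two-sided t-test of a vs b (per-pair differences)."""
    aa, ba = _as_1d(a, "a"), _as_1d(b, "b")
    if len(aa) != len(ba):
        raise ValueError("paired samples must have equal length")
    if len(aa) < 3:
        raise ValueError("need at least 3 pairs")
    d = aa - ba
    if d.var(ddof=1) == 0:
        if d.mean() == 0:
            return TTestResult(0.0, 1.0, len(d) - 1, len(d), len(d), degenerate=True)
        sign = 1.0 if d.mean() > 0 else -1.0
        return TTestResult(sign * math.inf, 0.0, len(d) - 1, len(d), len(d), degenerate=True)
    res = sps.ttest_rel(aa, ba)
    return TTestResult(float(res.statistic), float(res.pvalue), float(len(d) - 1), len(d), len(d))


def one_sample_t_test(x: Sequence[float], popmean: float = 0.0) -> TTestResult:
    xa = _as_1d(x, "x")
    if len(xa) < 3:
        raise ValueError("need at least 3 observations")
    if xa.var(ddof=1) == 0:
        if xa.mean() == popmean:
            return TTestResult(0.0, 1.0, len(xa) - 1, len(xa), degenerate=True)
        sign = 1.0 if xa.mean() > popmean else -1.0
        return TTestResult(sign * math.inf, 0.0, len(xa) - 1, len(xa), degenerate=True)
    res = sps.ttest_1samp(xa, popmean)
    return TTestResult(float(res.statistic), float(res.pvalue), float(len(xa) - 1), len(xa))


def linear_slope(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of y on x."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(xa) == 0:
        raise ValueError("x has zero variance")
    xm, ym = xa.mean(), ya.mean()
    slope = float(((xa - xm) * (ya - ym)).sum() / ((xa - xm) ** 2).sum())
    return slope, float(ym - slope * xm)


def normalize_by_clock_like(signature_counts: Mapping[str, float]) -> dict[str, float]:
    """Divide every non-clock signature count by the clock-like burden.

    The clock-like burden is SBS1 + SBS5 (the replication/age-associated
    signatures); normalizing by it removes the proliferative-history scale so
    damage-associated signatures can be compared across tumors. Clock-like
    entries are omitted from the output.
    """
    missing = [k for k in CLOCK_LIKE if k not in signature_counts]
    if missing:
        raise ValueError(f"missing clock-like signature counts: {missing}")
    denom = sum(float(signature_counts[k]) for k in CLOCK_LIKE)
    if denom <= 0:
        raise ValueError("clock-like burden (SBS1 + SBS5) must be positive")
    return {
        k: float(v) / denom for k, v in signature_counts.items() if k not in CLOCK_LIKE
    }
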