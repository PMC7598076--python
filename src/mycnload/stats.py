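"""Statistical primitives shared by the pipeline.

Each primitive is deliberately simple enough to verify against enumeration or
a closed form: percentile bootstrap CI of the mean, exact/approximate
two-sided Wilcoxon rank-sum, Welch's t, Benjamini-Hochberg step-up, and the
caliper tumor-volume formula V = 4/3 pi ((d1+d2)/4)^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigError

# Exact Wilcoxon enumeration is bounded to keep C(n, na) manageable.
EXACT_WILCOXON_MAX_MIN_N = 8
EXACT_WILCOXON_MAX_TOTAL = 20


@dataclass(frozen=True, slots=True)
class ConfidenceInterval:
    low: float
    high: float
    level: float
    n_iters: int
    seed: int


@dataclass(frozen=True, slots=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


def bootstrap_ci_mean(
    values: Sequence[float],
    iters: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> ConfidenceInterval:
    """Percentile bootstrap CI of the mean (resampling with replacement).

    Endpoints are the (1-level)/2 and 1-(1-level)/2 empirical percentiles of
    ``iters`` resample means, with linear interpolation between order
    statistics; the generator is seeded for reproducibility.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ConfigError("bootstrap_ci_mean requires at least one value")
    if iters < 1:
        raise ConfigError("iters must be >= 1")
    if not (0.0 < level < 1.0):
        raise ConfigError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = arr.size
    means = np.empty(iters, dtype=float)
    # chunked to bound the iters x n index matrix at ~2e7 entries
    chunk = max(1, int(2e7 // max(n, 1)))
    done = 0
    while done < iters:
        take = min(chunk, iters - done)
        idx = rng.integers(0, n, size=(take, n))
        means[done : done + take] = arr[idx].mean(axis=1)
        done += take
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return ConfidenceInterval(float(low), float(high), level, iters, seed)


def _rank_sum_exact_p(pooled_ranks: np.ndarray, na: int, observed: float) -> float:
    """Two-sided exact p for the rank-sum of group a by full enumeration.

    p = min(1, 2 * min(P(W <= w), P(W >= w))) over all C(n, na) assignments,
    with midranks so ties are handled identically to the observed statistic.
    """
    n = len(pooled_ranks)
    n_le = n_ge = total = 0
    tol = 1e-9
    for combo in combinations(range(n), na):
        w = pooled_ranks[list(combo)].sum()
        total += 1
        if w <= observed + tol:
            n_le += 1
        if w >= observed - tol:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided unpaired Wilcoxon (Mann-Whitney) rank-sum test.

    Small samples (min n <= 8 and total <= 20) use exact enumeration over all
    group assignments with midranks; larger samples use the normal
    approximation with tie and continuity corrections. The method tag records
    which path ran. The statistic reported is the rank-sum W of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:na].sum())
    if np.all(pooled == pooled[0]):  # no separation at all
        return TestResult(statistic=w, p_value=1.0, method="wilcoxon_exact")
    if min(na, nb) <= EXACT_WILCOXON_MAX_MIN_N and na + nb <= EXACT_WILCOXON_MAX_TOTAL:
        p = _rank_sum_exact_p(ranks, na, w)
        return TestResult(statistic=w, p_value=p, method="wilcoxon_exact")
    # scipy's asymptotic Mann-Whitney U applies the same tie + continuity
    # corrections as the classical normal approximation
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=w, p_value=float(res.pvalue), method="wilcoxon_normal")


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Welch's t test with Satterthwaite degrees of freedom.

    Degenerate zero-variance inputs follow the convention p = 1 when the
    means are equal and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("welch_t requires >= 2 observations per group")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va + vb == 0.0:
        if ma == mb:
            return TestResult(statistic=0.0, p_value=1.0, method="welch_t")
        t = math.inf if ma > mb else -math.inf
        return TestResult(statistic=t, p_value=0.0, method="welch_t")
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), p_value=min(1.0, p), method="welch_t")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    q(i) = min_{j >= i in sorted order} p(j) * m / j, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def tumor_volume(d1: float, d2: float) -> float:
    """Caliper tumor volume V = 4/3 pi ((d1 + d2) / 4)^3 (mm^3).

    d1 and d2 are the two perpendicular diameters in mm; the formula is
    symmetric in its arguments.
    """
    if d1 < 0 or d2 < 0:
        raise ConfigError("diameters must be nonnegative")
    return (4.0 / 3.0) * math.pi * ((d1 + d2) / 4.0) ** 3
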