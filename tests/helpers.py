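"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the most literal possible computation (per-bp arrays,
full enumeration, plain running sums) and share no code with the package's
optimized paths.
"""

from itertools import combinations

import numpy as np


def pileup_density(reads, region, total_mapped, ext_bp=200):
    """Per-base pileup oracle for region read density.

    Builds an explicit coverage array over the region from 3'-extended read
    footprints, sums it, and normalizes at the end.
    """
    cov = np.zeros(region.end - region.start, dtype=np.int64)
    for read in reads:
        iv = read.interval
        if iv.chrom != region.chrom:
            continue
        if iv.strand == "+":
            fs, fe = iv.start, iv.end + ext_bp
        else:
            fs, fe = max(0, iv.start - ext_bp), iv.end
        lo = max(fs, region.start) - region.start
        hi = min(fe, region.end) - region.start
        if hi > lo:
            cov[lo:hi] += 1
    total = int(cov.sum())
    density = total / len(cov) / (total_mapped / 1e6)
    return density, density * len(cov)


def track_auc_per_bp(track, region):
    """Per-bp summation oracle for track AUC over a region."""
    return sum(
        track.value_at(region.chrom, pos) for pos in range(region.start, region.end)
    )


def wilcoxon_exact_enumeration(a, b):
    """Two-sided exact rank-sum p by naive enumeration (midranks for ties)."""
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, n = len(a), len(pooled)
    w_obs = ranks[:na].sum()
    n_le = n_ge = total = 0
    for combo in combinations(range(n), na):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def running_sum_es(metric_sorted_desc, hit_mask, weight=1.0):
    """Literal step-by-step enrichment running sum; returns the extremum."""
    r = [abs(x) ** weight for x in metric_sorted_desc]
    hits = [r[i] for i in range(len(r)) if hit_mask[i]]
    hit_total = sum(hits)
    n_miss = len(r) - len(hits)
    running, best = 0.0, 0.0
    for i in range(len(r)):
        if hit_mask[i]:
            running += (r[i] / hit_total) if hit_total > 0 else 1.0 / len(hits)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
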