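"""Spike-in cell-count normalization, signature scoring and enrichment.

ERCC spike-ins are added in proportion to cell number, so size factors
derived from spike rows recover global (amplitude) expression shifts that
per-sample depth normalization hides: after dividing by spike factors, a
drug that halves the whole transcriptome shows a median log2 fold change of
-1 instead of ~0. The enrichment analysis ranks genes by the signal2noise
metric and measures gene-set concentration with a weighted running sum,
assigning significance by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genomics_io import ExpressionTable

logger = logging.getLogger(__name__)

S2N_SIGMA_FLOOR_FRACTION = 0.2  # sigma floored at 0.2*|mean| (0.2 if mean == 0)


@dataclass
class SizeFactors:
    """Per-sample scaling factors with geometric mean 1."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise DataError("size factors must be positive")


def _rescale_geomean(factors: pd.Series) -> pd.Series:
    return factors / np.exp(np.log(factors.to_numpy()).mean())


def spike_size_factors(expr: ExpressionTable) -> SizeFactors:
    """Median-of-ratios size factors computed on spike-in rows only.

    Each spike's values are divided by its geometric mean across samples;
    the per-sample factor is the median of those ratios, rescaled so the
    factors have geometric mean 1. Spikes with a zero in any sample are
    dropped with a warning; fewer than 2 usable spikes is an error.
    """
    spikes = expr.spikes()
    usable = spikes.loc[(spikes > 0).all(axis=1)]
    n_dropped = len(spikes) - len(usable)
    if n_dropped:
        logger.warning("dropped %d spike rows with zero values", n_dropped)
    if len(usable) < 2:
        raise ConfigError(
            f"need >= 2 spike rows nonzero in every sample, have {len(usable)}"
        )
    log_vals = np.log(usable.to_numpy())
    ratios = np.exp(log_vals - log_vals.mean(axis=1, keepdims=True))
    factors = pd.Series(np.median(ratios, axis=0), index=usable.columns)
    return SizeFactors(_rescale_geomean(factors), method="spike_median_ratio")


def total_size_factors(expr: ExpressionTable) -> SizeFactors:
    """Library-size factors from total non-spike signal (geometric mean 1).

    This is the depth-style normalization that a global amplitude shift
    silently absorbs; provided as the contrast to spike-based factors.
    """
    totals = expr.nonspike().sum(axis=0)
    if (totals <= 0).any():
        raise DataError("every sample needs positive total non-spike signal")
    return SizeFactors(_rescale_geomean(totals), method="total_signal")


def apply_size_factors(expr: ExpressionTable, size_factors: SizeFactors) -> ExpressionTable:
    """Divide every sample column by its size factor."""
    missing = [s for s in expr.sample_ids if s not in size_factors.factors.index]
    if missing:
        raise ConfigError(f"no size factor for samples: {missing}")
    return expr.with_values(expr.values / size_factors.factors[expr.values.columns])


@dataclass
class SignatureScore:
    """Median-based log2 response of a gene set between two conditions."""

    set_name: str
    treated: str
    control: str
    score: float
    gene_log2fc: pd.Series  # per-member log2fc, for box-plot statistics
    n_members_used: int
    n_members_missing: int


def signature_score(
    expr: ExpressionTable,
    gene_set: set[str],
    treated: str,
    control: str,
    set_name: str = "signature",
    eps: float = 1.0,
) -> SignatureScore:
    """log2((median_treated + eps) / (median_control + eps)) over set members.

    Condition means are taken per gene first, then the median across set
    members per condition. Members absent from the table are skipped with a
    warning; an empty intersection is a data error. The per-gene log2fc
    vector is also returned for box-plot style summaries.
    """
    present = sorted(gene_set & set(expr.nonspike().index))
    n_missing = len(gene_set) - len(present)
    if not present:
        raise DataError(f"gene set {set_name!r} has no members in the table")
    if n_missing:
        logger.warning("gene set %s: %d members missing from table", set_name, n_missing)
    mean_t = expr.condition_means(treated).loc[present]
    mean_c = expr.condition_means(control).loc[present]
    score = float(np.log2((np.median(mean_t) + eps) / (np.median(mean_c) + eps)))
    gene_log2fc = np.log2((mean_t + eps) / (mean_c + eps))
    return SignatureScore(
        set_name=set_name,
        treated=treated,
        control=control,
        score=score,
        gene_log2fc=gene_log2fc,
        n_members_used=len(present),
        n_members_missing=n_missing,
    )


def _floored_std(std: np.ndarray, mean: np.ndarray) -> np.ndarray:
    floor = np.where(
        mean != 0, S2N_SIGMA_FLOOR_FRACTION * np.abs(mean), S2N_SIGMA_FLOOR_FRACTION
    )
    return np.maximum(std, floor)


def signal2noise(a, b) -> float:
    """(mu_a - mu_b) / (sigma_a' + sigma_b') with GSEA-style sigma floors.

    sigma' = max(sigma, 0.2*|mu|), or max(sigma, 0.2) when mu = 0; sample
    standard deviations use ddof=1. Requires >= 2 replicates per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("signal2noise requires >= 2 replicates per group")
    sa = _floored_std(np.array(a.std(ddof=1)), np.array(a.mean()))
    sb = _floored_std(np.array(b.std(ddof=1)), np.array(b.mean()))
    return float((a.mean() - b.mean()) / (sa + sb))


def _signal2noise_matrix(values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    va, vb = values[:, idx_a], values[:, idx_b]
    ma, mb = va.mean(axis=1), vb.mean(axis=1)
    sa = _floored_std(va.std(axis=1, ddof=1), ma)
    sb = _floored_std(vb.std(axis=1, ddof=1), mb)
    return (ma - mb) / (sa + sb)


def enrichment_score(ranked_metric: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """Extremum of the weighted running sum over a ranked gene list.

    Hits increment by |r|^weight normalized to the set's total |r|^weight;
    misses decrement by 1/(N - set size). The score is the running-sum value
    of largest magnitude, in [-1, 1].
    """
    r = np.abs(np.asarray(ranked_metric, dtype=float)) ** weight
    hit_mask = np.asarray(hit_mask, dtype=bool)
    n_hit = int(hit_mask.sum())
    n = r.size
    if n_hit == 0:
        raise DataError("gene set has no members in the ranking")
    hit_total = r[hit_mask].sum()
    steps = np.empty(n, dtype=float)
    if hit_total > 0:
        steps[hit_mask] = r[hit_mask] / hit_total
    else:  # all-zero metric inside the set: spread hits evenly
        steps[hit_mask] = 1.0 / n_hit
    if n_hit < n:
        steps[~hit_mask] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class GseaResult:
    set_name: str
    es: float
    nominal_p: float
    n_perm: int
    seed: int
    perm_mode: str
    n_genes: int
    set_size: int


def gsea_lite(
    expr: ExpressionTable,
    treated: str,
    control: str,
    gene_set: set[str],
    set_name: str = "set",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Minimal gene-set enrichment: signal2noise ranking + permutation p.

    All non-spike genes are ranked by signal2noise(treated, control),
    descending, ties broken by gene id for determinism. The nominal p-value
    is (1 + #{|ES*| >= |ES|}) / (n_perm + 1), using phenotype (sample-label)
    permutations when each condition has >= 4 samples and random gene-set
    permutations of equal size otherwise; the mode used is recorded.
    """
    cols_t = expr.samples_of(treated)
    cols_c = expr.samples_of(control)
    if len(cols_t) < 2 or len(cols_c) < 2:
        raise ConfigError("each condition needs >= 2 samples for signal2noise")
    table = expr.nonspike()
    values = table.to_numpy(dtype=float)
    sample_pos = {s: i for i, s in enumerate(table.columns)}
    idx_t = np.array([sample_pos[s] for s in cols_t])
    idx_c = np.array([sample_pos[s] for s in cols_c])

    metric = _signal2noise_matrix(values, idx_t, idx_c)
    gene_ids = np.array(table.index)
    order = np.lexsort((gene_ids, -metric))  # descending metric, id tiebreak
    ranked_metric = metric[order]
    ranked_ids = gene_ids[order]
    in_set = np.isin(ranked_ids, list(gene_set))
    set_size = int(in_set.sum())
    if set_size < 2:
        raise DataError(
            f"gene set {set_name!r}: need >= 2 members in the table, have {set_size}"
        )
    es = enrichment_score(ranked_metric, in_set, weight)

    rng = np.random.default_rng(seed)
    n = len(ranked_ids)
    n_extreme = 0
    if min(len(cols_t), len(cols_c)) >= 4:
        perm_mode = "phenotype"
        all_idx = np.concatenate([idx_t, idx_c])
        set_ids = list(gene_set)
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            pm = _signal2noise_matrix(values, perm[: len(idx_t)], perm[len(idx_t) :])
            p_order = np.lexsort((gene_ids, -pm))
            p_in_set = np.isin(gene_ids[p_order], set_ids)
            es_star = enrichment_score(pm[p_order], p_in_set, weight)
            if abs(es_star) >= abs(es):
                n_extreme += 1
    else:
        perm_mode = "gene_set"
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=set_size, replace=False)] = True
            es_star = enrichment_score(ranked_metric, mask, weight)
            if abs(es_star) >= abs(es):
                n_extreme += 1
    nominal_p = (1 + n_extreme) / (n_perm + 1)
    return GseaResult(
        set_name=set_name,
        es=es,
        nominal_p=float(nominal_p),
        n_perm=n_perm,
        seed=seed,
        perm_mode=perm_mode,
        n_genes=n,
        set_size=set_size,
    )


def signature_comparison(
    scores: list[SignatureScore],
) -> pd.DataFrame:
    """Box-plot statistics and pairwise Welch tests between signature vectors.

    Returns one row per pair of signatures with Welch's two-sided t p-value,
    BH-adjusted across the comparisons, plus quartiles of each vector
    (whiskers at 1.5x IQR are a plotting convention left to callers).
    """
    from .stats import bh_adjust, welch_t

    rows = []
    for i in range(len(scores)):
        for j in range(i + 1, len(scores)):
            a, b = scores[i], scores[j]
            res = welch_t(a.gene_log2fc.to_numpy(), b.gene_log2fc.to_numpy())
            rows.append(
                {
                    "set_a": a.set_name,
                    "set_b": b.set_name,
                    "median_a": float(a.gene_log2fc.median()),
                    "median_b": float(b.gene_log2fc.median()),
                    "q1_a": float(a.gene_log2fc.quantile(0.25)),
                    "q3_a": float(a.gene_log2fc.quantile(0.75)),
                    "q1_b": float(b.gene_log2fc.quantile(0.25)),
                    "q3_b": float(b.gene_log2fc.quantile(0.75)),
                    "t_statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df
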