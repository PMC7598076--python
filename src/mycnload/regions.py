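"""Promoter/enhancer classification of H3K27ac peaks and per-gene MYCN load.

Active promoters carry an H3K27ac peak overlapping the +/-1 kb window around
the TSS; H3K27ac peaks outside every promoter window are enhancers. A gene's
MYCN load is the cumulative MYCN signal (rpm x bp) over its promoter window
plus, by default, over the enhancer-class peaks whose midpoints lie within
+/-50 kb of the TSS (promoter bp excluded from enhancer footprints so the two
components are additive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError
from .genomics_io import (
    STRAND_PLUS,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    Peak,
)
from .signal_quant import DEFAULT_EXT_BP, SignalTrack


@dataclass(frozen=True, slots=True)
class LoadConfig:
    """Window geometry for promoter/enhancer load scoring.

    promoter_halfwidth: bp either side of the TSS counted as promoter (1 kb).
    enhancer_halfwidth: bp either side of the TSS searched for enhancers (50 kb).
    ext_bp: read extension used when the MYCN track was built (200 bp).
    enhancer_mode: "peaks" sums MYCN signal over enhancer-class H3K27ac peaks
    in the window; "window" takes raw MYCN AUC over the whole +/-50 kb window
    (promoter bp excluded in both modes).
    """

    promoter_halfwidth: int = 1000
    enhancer_halfwidth: int = 50_000
    ext_bp: int = DEFAULT_EXT_BP
    enhancer_mode: str = "peaks"

    def __post_init__(self) -> None:
        if not (0 < self.promoter_halfwidth < self.enhancer_halfwidth):
            raise ConfigError(
                "need 0 < promoter_halfwidth < enhancer_halfwidth "
                f"(got {self.promoter_halfwidth}, {self.enhancer_halfwidth})"
            )
        if self.ext_bp < 0:
            raise ConfigError("ext_bp must be nonnegative")
        if self.enhancer_mode not in ("peaks", "window"):
            raise ConfigError(f"unknown enhancer_mode {self.enhancer_mode!r}")


def tss_of(gene: GeneModel) -> int:
    """Strand-dependent transcription start site (0-based position)."""
    iv = gene.interval
    return iv.start if iv.strand == STRAND_PLUS else iv.end - 1


def promoter_window(gene: GeneModel, cfg: LoadConfig) -> GenomicInterval:
    """[tss - halfwidth, tss + halfwidth), clipped at chromosome start."""
    tss = tss_of(gene)
    return GenomicInterval(
        gene.interval.chrom,
        max(0, tss - cfg.promoter_halfwidth),
        tss + cfg.promoter_halfwidth,
    )


@dataclass
class RegulatoryClassification:
    """Partition of H3K27ac peaks into promoter- and enhancer-class.

    ``promoter_peak_genes[i]`` holds the gene ids whose promoter window the
    i-th promoter peak overlaps. The two peak lists partition the input.
    """

    promoter_peaks: list[Peak]
    promoter_peak_genes: list[frozenset[str]]
    enhancer_peaks: list[Peak]
    promoter_active: dict[str, bool]

    @property
    def n_peaks(self) -> int:
        return len(self.promoter_peaks) + len(self.enhancer_peaks)


def classify_peaks(
    peaks: list[Peak], genes: list[GeneModel], cfg: LoadConfig | None = None
) -> RegulatoryClassification:
    """Promoter-class iff a peak overlaps (>=1 bp) any gene's promoter window.

    A peak overlapping two genes' windows is recorded against both; a gene is
    promoter-active iff at least one peak overlaps its window.
    """
    cfg = cfg or LoadConfig()
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        win = promoter_window(gene, cfg)
        trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, gene.gene_id)
    promoter_active = {g.gene_id: False for g in genes}
    promoter_peaks: list[Peak] = []
    promoter_peak_genes: list[frozenset[str]] = []
    enhancer_peaks: list[Peak] = []
    for peak in peaks:
        iv = peak.interval
        tree = trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree is not None else set()
        if hits:
            gene_ids = frozenset(h.data for h in hits)
            promoter_peaks.append(peak)
            promoter_peak_genes.append(gene_ids)
            for gid in gene_ids:
                promoter_active[gid] = True
        else:
            enhancer_peaks.append(peak)
    return RegulatoryClassification(
        promoter_peaks=promoter_peaks,
        promoter_peak_genes=promoter_peak_genes,
        enhancer_peaks=enhancer_peaks,
        promoter_active=promoter_active,
    )


@dataclass(frozen=True, slots=True)
class GeneLoad:
    """Per-gene cumulative MYCN signal (rpm x bp) split by compartment."""

    gene_id: str
    promoter_load: float
    enhancer_load: float

    @property
    def total_load(self) -> float:
        return self.promoter_load + self.enhancer_load


def _interval_minus_window(iv: GenomicInterval, win: GenomicInterval):
    """Pieces of ``iv`` outside ``win`` (0, 1 or 2 intervals)."""
    if iv.chrom != win.chrom or iv.end <= win.start or iv.start >= win.end:
        yield iv
        return
    if iv.start < win.start:
        yield GenomicInterval(iv.chrom, iv.start, win.start)
    if iv.end > win.end:
        yield GenomicInterval(iv.chrom, win.end, iv.end)


def gene_load(
    track: SignalTrack,
    gene: GeneModel,
    classification: RegulatoryClassification,
    cfg: LoadConfig | None = None,
) -> GeneLoad:
    """MYCN load of one gene from a normalized (rpm/bp) track.

    promoter_load: track AUC over the +/-1 kb promoter window.
    enhancer_load ("peaks" mode): sum over enhancer-class peaks whose midpoint
    falls in [tss - 50 kb, tss + 50 kb), of the AUC over the peak footprint
    with promoter-window bp removed. "window" mode: AUC over the whole +/-50 kb
    window minus the promoter window.
    """
    cfg = cfg or LoadConfig()
    tss = tss_of(gene)
    chrom = gene.interval.chrom
    prom_win = promoter_window(gene, cfg)
    promoter_load = track.auc(prom_win)
    lo, hi = tss - cfg.enhancer_halfwidth, tss + cfg.enhancer_halfwidth
    if cfg.enhancer_mode == "window":
        big = GenomicInterval(chrom, max(0, lo), hi)
        enhancer_load = sum(
            track.auc(piece) for piece in _interval_minus_window(big, prom_win)
        )
    else:
        enhancer_load = 0.0
        for peak in classification.enhancer_peaks:
            if peak.interval.chrom != chrom:
                continue
            if not (lo <= peak.midpoint < hi):
                continue
            for piece in _interval_minus_window(peak.interval, prom_win):
                enhancer_load += track.auc(piece)
    return GeneLoad(gene.gene_id, float(promoter_load), float(enhancer_load))


def compute_loads(
    track: SignalTrack,
    genes: list[GeneModel],
    classification: RegulatoryClassification,
    cfg: LoadConfig | None = None,
) -> pd.DataFrame:
    """Per-gene loads for all genes, with enhancer peaks indexed by midpoint.

    Returns a DataFrame indexed by gene_id with columns promoter_load,
    enhancer_load, total_load, promoter_active.
    """
    cfg = cfg or LoadConfig()
    by_chrom: dict[str, tuple[np.ndarray, list[Peak]]] = {}
    if cfg.enhancer_mode == "peaks":
        tmp: dict[str, list[Peak]] = {}
        for peak in classification.enhancer_peaks:
            tmp.setdefault(peak.interval.chrom, []).append(peak)
        for chrom, plist in tmp.items():
            plist.sort(key=lambda p: p.midpoint)
            by_chrom[chrom] = (np.array([p.midpoint for p in plist]), plist)
    rows = []
    for gene in genes:
        tss = tss_of(gene)
        chrom = gene.interval.chrom
        prom_win = promoter_window(gene, cfg)
        promoter_load = track.auc(prom_win)
        lo, hi = tss - cfg.enhancer_halfwidth, tss + cfg.enhancer_halfwidth
        enhancer_load = 0.0
        if cfg.enhancer_mode == "window":
            big = GenomicInterval(chrom, max(0, lo), hi)
            enhancer_load = sum(
                track.auc(piece) for piece in _interval_minus_window(big, prom_win)
            )
        elif chrom in by_chrom:
            mids, plist = by_chrom[chrom]
            i0 = int(np.searchsorted(mids, lo, side="left"))
            i1 = int(np.searchsorted(mids, hi, side="left"))  # midpoint < hi
            for peak in plist[i0:i1]:
                for piece in _interval_minus_window(peak.interval, prom_win):
                    enhancer_load += track.auc(piece)
        rows.append(
            (
                gene.gene_id,
                float(promoter_load),
                float(enhancer_load),
                bool(classification.promoter_active.get(gene.gene_id, False)),
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "promoter_load", "enhancer_load", "promoter_active"]
    ).set_index("gene_id")
    df.insert(2, "total_load", df["promoter_load"] + df["enhancer_load"])
    return df


def active_expressed_genes(
    genes: list[GeneModel],
    classification: RegulatoryClassification,
    expression: ExpressionTable,
    control_condition: str,
) -> set[str]:
    """Genes that are promoter-active AND in the top 50% of control expression.

    The percentile is computed over mean control-condition expression of all
    non-spike genes (linear interpolation); the boundary is inclusive, so all
    genes tied at the median qualify.
    """
    control_samples = expression.samples_of(control_condition)
    if not control_samples:
        raise ConfigError(f"no samples with condition {control_condition!r}")
    means = expression.nonspike()[control_samples].mean(axis=1)
    threshold = float(np.percentile(means.to_numpy(), 50))
    expressed = set(means.index[means >= threshold])
    return {
        g.gene_id
        for g in genes
        if classification.promoter_active.get(g.gene_id, False)
        and g.gene_id in expressed
    }
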