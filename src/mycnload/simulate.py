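"""Seeded synthetic inputs with a planted load -> response relationship.

The generator emulates the structure of the real experiment: a genome of
non-overlapping genes; H3K27ac peaks at every promoter plus 0-3 enhancer
peaks within +/-50 kb of each TSS; MYCN reads whose per-gene intensity is
proportional to a heavy-tailed (log-normal) planted load; an expression
matrix where the treated/control log2 fold change is

    true_log2fc_g = log2(alpha) + beta * z(lambda_g) + eps_g,

i.e. a global amplitude shift ``alpha`` (treated transcriptome scale),
a slope ``beta`` on the standardized load, and gene noise eps ~ N(0, sigma);
ERCC spikes have identical expected values in all samples (they track cell
number, not transcriptome amplitude), which is what makes spike-based
normalization able to expose ``alpha``. Half-lives are drawn so high-load
genes tend to be short-lived, mirroring the observation that short-lived
transcripts respond fastest to elongation blockade.

The ground truth is exported so recovery tests can compare pipeline output
with the planted parameters. All outputs are deterministic per (seed,
parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genomics_io import (
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    Peak,
    ReadAlignment,
    write_bed,
    write_expression_table,
    write_gene_models,
    write_gmt,
    write_halflife_table,
)

# Defaults are the reference study conditions for all recovery tests.
DEFAULT_N_GENES = 5000
DEFAULT_CHROM_LENGTH = 100_000_000
DEFAULT_LOAD_MU = 5.0
DEFAULT_LOAD_SIGMA = 1.2
DEFAULT_BETA = -0.3
DEFAULT_SIGMA = 0.1
DEFAULT_ALPHA = 0.7
DEFAULT_N_REPS = 3
DEFAULT_SPIKE_COUNT = 20
DEFAULT_READS_PER_UNIT_LOAD = 0.5
DEFAULT_BACKGROUND_PER_KB = 0.01
READ_LENGTH = 50
TSS_MARGIN = 51_000  # keeps every +/-50 kb window (plus extension) in-bounds
CHROM = "chr1"


def generate_genome(
    n_genes: int,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    seed: int = 0,
    chrom: str = CHROM,
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes with >= 51 kb end margins.

    Genes occupy a jittered grid: the usable span is divided into equal
    slots and each gene lands at a random position inside its slot, so
    inter-gene spacing is as even as the density allows (at low density the
    +/-50 kb enhancer windows of neighbors stay disjoint; at high density
    window overlap is unavoidable and deliberate). Gene lengths are uniform
    in [2 kb, min(15 kb, 3/4 slot)]; deterministic per seed.
    """
    if n_genes < 0:
        raise ConfigError("n_genes must be nonnegative")
    if n_genes == 0:
        return []
    rng = np.random.default_rng(seed)
    usable = chrom_length - 2 * TSS_MARGIN
    slot = usable // n_genes
    max_len = min(15_000, int(0.75 * slot))
    if usable <= 0 or max_len < 2000:
        raise ConfigError(
            f"cannot pack {n_genes} genes into {chrom_length} bp with margins"
        )
    lengths = rng.integers(2000, max_len + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = []
    for i in range(n_genes):
        slot_start = TSS_MARGIN + i * slot
        start = slot_start + int(rng.integers(0, slot - int(lengths[i])))
        end = start + int(lengths[i])
        genes.append(
            GeneModel(f"G{i + 1:05d}", GenomicInterval(chrom, start, end, strands[i]))
        )
    return genes


def _tss(gene: GeneModel) -> int:
    iv = gene.interval
    return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class ChipSim:
    """Simulated ChIP inputs plus the planted per-gene loads."""

    reads: list[ReadAlignment]
    read_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    peaks: list[Peak]
    loads: pd.Series  # gene_id -> planted lambda (rpm x bp scale)
    total_mapped: int


def generate_chip(
    genes: list[GeneModel],
    load_mu: float = DEFAULT_LOAD_MU,
    load_sigma: float = DEFAULT_LOAD_SIGMA,
    reads_per_unit_load: float = DEFAULT_READS_PER_UNIT_LOAD,
    background_per_kb: float = DEFAULT_BACKGROUND_PER_KB,
    seed: int = 0,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
) -> ChipSim:
    """H3K27ac peaks, MYCN reads and planted loads for a gene set.

    Every gene gets a promoter H3K27ac peak (so it classifies active) and
    0-3 enhancer peaks with midpoints 2-48 kb from the TSS (clear of the
    +/-1 kb promoter window). Per-gene MYCN read counts are Poisson with
    intensity reads_per_unit_load * lambda_g, the reads placed uniformly in
    the gene's peaks; uniform background reads are added at
    ``background_per_kb`` expected reads per kb of chromosome.
    """
    if reads_per_unit_load < 0 or background_per_kb < 0:
        raise ConfigError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(genes)
    lam = rng.lognormal(load_mu, load_sigma, size=n)

    peaks: list[Peak] = []
    peak_regions: list[list[tuple[int, int]]] = []  # per gene: read-placement regions
    for i, gene in enumerate(genes):
        tss = _tss(gene)
        regions: list[tuple[int, int]] = []
        # promoter peak kept inside the +/-1 kb window: center +/-300, hw <= 650
        center = tss + int(rng.integers(-300, 301))
        hw = int(rng.integers(250, 651))
        pstart, pend = max(0, center - hw), center + hw
        peaks.append(Peak(GenomicInterval(gene.interval.chrom, pstart, pend),
                          name=f"{gene.gene_id}_prom"))
        regions.append((pstart, pend))
        for j in range(int(rng.integers(0, 4))):
            offset = int(rng.integers(2000, 48_001)) * (1 if rng.random() < 0.5 else -1)
            mid = tss + offset
            hw = int(rng.integers(250, 1001))
            estart, eend = max(0, mid - hw), mid + hw
            peaks.append(Peak(GenomicInterval(gene.interval.chrom, estart, eend),
                              name=f"{gene.gene_id}_enh{j + 1}"))
            regions.append((estart, eend))
        peak_regions.append(regions)

    # Reads are placed so that the 3'-extended footprint (read + default
    # 200 bp extension) stays inside the generating peak; every signal read
    # then contributes its full footprint to the load windows.
    ext = 200
    starts: list[np.ndarray] = []
    strands_parts: list[np.ndarray] = []
    for i, gene in enumerate(genes):
        n_reads = int(rng.poisson(reads_per_unit_load * lam[i]))
        if n_reads == 0:
            continue
        regions = peak_regions[i]
        which = rng.integers(0, len(regions), size=n_reads)
        strand = np.where(rng.random(n_reads) < 0.5, 1, -1)
        r_lo = np.array([r[0] for r in regions])[which]
        r_hi = np.array([r[1] for r in regions])[which]
        lo = np.where(strand == 1, r_lo, r_lo + ext)
        hi = np.where(strand == 1, r_hi - READ_LENGTH - ext, r_hi - READ_LENGTH)
        hi = np.maximum(hi, lo + 1)
        starts.append(lo + (rng.random(n_reads) * (hi - lo)).astype(np.int64))
        strands_parts.append(strand)
    n_bg = int(rng.poisson(background_per_kb * chrom_length / 1000))
    if n_bg:
        starts.append(rng.integers(0, chrom_length - READ_LENGTH, size=n_bg))
        strands_parts.append(np.where(rng.random(n_bg) < 0.5, 1, -1))
    all_starts = (
        np.concatenate(starts).astype(np.int64) if starts else np.empty(0, dtype=np.int64)
    )
    all_ends = all_starts + READ_LENGTH
    all_strands = (
        np.concatenate(strands_parts) if strands_parts else np.empty(0, dtype=np.int64)
    )
    chrom = genes[0].interval.chrom if genes else CHROM
    total_mapped = max(1, len(all_starts))
    reads = [
        ReadAlignment(
            GenomicInterval(chrom, int(s), int(e), "+" if st == 1 else "-")
        )
        for s, e, st in zip(all_starts, all_ends, all_strands)
    ]
    return ChipSim(
        reads=reads,
        read_arrays={chrom: (all_starts, all_ends, all_strands)},
        peaks=peaks,
        loads=pd.Series(lam, index=[g.gene_id for g in genes], name="true_load"),
        total_mapped=total_mapped,
    )


def standardized_load(loads: pd.Series) -> pd.Series:
    """z-score of the planted loads across genes."""
    lam = loads.to_numpy(dtype=float)
    return pd.Series((lam - lam.mean()) / lam.std(), index=loads.index)


def generate_expression(
    genes: list[GeneModel],
    loads: pd.Series,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    sigma: float = DEFAULT_SIGMA,
    n_reps: int = DEFAULT_N_REPS,
    spike_count: int = DEFAULT_SPIKE_COUNT,
    seed: int = 0,
) -> tuple[ExpressionTable, pd.DataFrame, pd.Series]:
    """Expression table with ERCC spikes, the truth table, and half-lives.

    Control FPKM is log-normal per gene; treated FPKM multiplies it by
    2^(true_log2fc). Replicate noise is multiplicative 2^N(0, sigma), so
    sigma = 0 makes every realized fold change exact. Spikes get the same
    expected value in all samples (cell-number anchoring): the global alpha
    applies to genes only. Half-lives are log-normal with a negative
    coefficient on z(load), so high-load genes tend to be short-lived.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be >= 2")
    if spike_count < 2:
        raise ConfigError("spike_count must be >= 2")
    if alpha <= 0 or sigma < 0:
        raise ConfigError("alpha must be > 0 and sigma >= 0")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    lam = loads.loc[gene_ids]
    z = standardized_load(lam).to_numpy() if n > 1 else np.zeros(n)

    baseline = rng.lognormal(3.0, 1.0, size=n)  # median ~20 FPKM
    eps_g = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    true_log2fc = np.log2(alpha) + beta * z + eps_g

    def noisy(base: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return base.copy()
        return base * np.exp2(rng.normal(0.0, sigma, size=base.shape))

    control = np.column_stack([noisy(baseline) for _ in range(n_reps)])
    treated_base = baseline * np.exp2(true_log2fc)
    treated = np.column_stack([noisy(treated_base) for _ in range(n_reps)])

    spike_ids = [f"ERCC-{i + 1:05d}" for i in range(spike_count)]
    spike_base = rng.lognormal(4.0, 1.0, size=spike_count)
    spike_control = np.column_stack([noisy(spike_base) for _ in range(n_reps)])
    spike_treated = np.column_stack([noisy(spike_base) for _ in range(n_reps)])

    sample_ids = [f"control_{r + 1}" for r in range(n_reps)] + [
        f"treated_{r + 1}" for r in range(n_reps)
    ]
    values = pd.DataFrame(
        np.vstack(
            [
                np.hstack([control, treated]),
                np.hstack([spike_control, spike_treated]),
            ]
        ),
        index=gene_ids + spike_ids,
        columns=sample_ids,
    )
    condition_of = {s: ("control" if s.startswith("control") else "treated") for s in sample_ids}
    is_spike = pd.Series(
        [False] * n + [True] * spike_count, index=values.index, dtype=bool
    )
    expr = ExpressionTable(values=values, condition_of=condition_of, is_spike=is_spike)

    log_hl = np.log(9.0) - 0.6 * z + rng.normal(0.0, 0.6, size=n)
    halflives = pd.Series(np.exp(log_hl), index=gene_ids, name="halflife_h")

    truth = pd.DataFrame(
        {
            "true_load": lam.to_numpy(),
            "z_load": z,
            "true_log2fc": true_log2fc,
            "baseline_fpkm": baseline,
            "halflife_h": halflives.to_numpy(),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth.attrs.update({"alpha": alpha, "beta": beta, "sigma": sigma})
    return expr, truth, halflives


def synthetic_gene_sets(
    truth: pd.DataFrame, set_size: int = 40, seed: int = 0
) -> dict[str, set[str]]:
    """Synthetic "ADRN"/"MES" sets: high-load vs low-load genes.

    With beta < 0 the ADRN set is preferentially downregulated, mirroring the
    adrenergic-vs-mesenchymal signature contrast.
    """
    rng = np.random.default_rng(seed)
    ranked = truth.sort_values("true_load", ascending=False).index
    pool = max(set_size, min(500, len(ranked) // 2))
    adrn = set(rng.choice(list(ranked[:pool]), size=min(set_size, pool), replace=False))
    mes = set(rng.choice(list(ranked[-pool:]), size=min(set_size, pool), replace=False))
    return {"ADRN": adrn, "MES": mes}


@dataclass
class SyntheticDataset:
    """A fully simulated input bundle, optionally written to disk."""

    genes: list[GeneModel]
    chip: ChipSim
    expression: ExpressionTable
    truth: pd.DataFrame
    halflives: pd.Series
    gene_sets: dict[str, set[str]]
    params: dict
    paths: dict[str, str] = field(default_factory=dict)


def simulate_dataset(
    out_dir: str | Path | None = None,
    n_genes: int = DEFAULT_N_GENES,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    load_mu: float = DEFAULT_LOAD_MU,
    load_sigma: float = DEFAULT_LOAD_SIGMA,
    reads_per_unit_load: float = DEFAULT_READS_PER_UNIT_LOAD,
    background_per_kb: float = DEFAULT_BACKGROUND_PER_KB,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    sigma: float = DEFAULT_SIGMA,
    n_reps: int = DEFAULT_N_REPS,
    spike_count: int = DEFAULT_SPIKE_COUNT,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a complete dataset; write standard-format files if ``out_dir``.

    Child seeds for the genome, ChIP, expression and gene-set stages are
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_chip, s_expr, s_sets = (int(x) for x in ss.generate_state(4) % (2**31))
    genes = generate_genome(n_genes, chrom_length, seed=s_genome)
    chip = generate_chip(
        genes,
        load_mu=load_mu,
        load_sigma=load_sigma,
        reads_per_unit_load=reads_per_unit_load,
        background_per_kb=background_per_kb,
        seed=s_chip,
        chrom_length=chrom_length,
    )
    expr, truth, halflives = generate_expression(
        genes,
        chip.loads,
        alpha=alpha,
        beta=beta,
        sigma=sigma,
        n_reps=n_reps,
        spike_count=spike_count,
        seed=s_expr,
    )
    gene_sets = synthetic_gene_sets(truth, seed=s_sets)
    params = {
        "n_genes": n_genes,
        "chrom_length": chrom_length,
        "load_mu": load_mu,
        "load_sigma": load_sigma,
        "reads_per_unit_load": reads_per_unit_load,
        "background_per_kb": background_per_kb,
        "alpha": alpha,
        "beta": beta,
        "sigma": sigma,
        "n_reps": n_reps,
        "spike_count": spike_count,
        "seed": seed,
        "total_mapped": chip.total_mapped,
        "read_length": READ_LENGTH,
    }
    ds = SyntheticDataset(
        genes=genes,
        chip=chip,
        expression=expr,
        truth=truth,
        halflives=halflives,
        gene_sets=gene_sets,
        params=params,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": str(out / "genes.refflat"),
            "h3k27ac_peaks": str(out / "h3k27ac_peaks.bed"),
            "mycn_reads": str(out / "mycn_reads.bed"),
            "expression": str(out / "expression.tsv"),
            "halflife": str(out / "halflife.tsv"),
            "gene_sets": str(out / "gene_sets.gmt"),
            "truth": str(out / "truth.tsv"),
            "params": str(out / "params.json"),
        }
        write_gene_models(genes, paths["genes"], dialect="refFlat")
        write_bed(chip.peaks, paths["h3k27ac_peaks"])
        write_bed(chip.reads, paths["mycn_reads"])
        write_expression_table(expr, paths["expression"])
        write_halflife_table(halflives, paths["halflife"])
        write_gmt(gene_sets, paths["gene_sets"])
        truth.to_csv(paths["truth"], sep="\t", float_format="%.10g")
        with open(paths["params"], "w") as fh:
            json.dump(params, fh, indent=2, sort_keys=True)
            fh.write("\n")
        ds.paths = paths
    return ds
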