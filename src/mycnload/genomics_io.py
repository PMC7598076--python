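"""Readers/writers for the interval and expression formats the pipeline consumes.

All genomic coordinates are held 0-based half-open internally. BED is adopted
verbatim (it is already half-open); GTF start coordinates are shifted by -1 at
parse time. Chromosome names are compared as exact strings; an optional flag
strips a leading ``chr`` prefix for callers that need to reconcile sources.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_PLUS, STRAND_MINUS, STRAND_NONE})

DEFAULT_SPIKE_PREFIX = "ERCC-"


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bp with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A stranded aligned read, the input to signal quantification."""

    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError("aligned reads must be stranded (+ or -)")


@dataclass(frozen=True, slots=True)
class Peak:
    """An enrichment region (e.g. an H3K27ac or MYCN peak call)."""

    interval: GenomicInterval
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not (self.score >= 0):
            raise ValueError("peak score must be nonnegative")

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene reduced to its transcribed span; the TSS is strand-dependent."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in (STRAND_PLUS, STRAND_MINUS):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class ExpressionTable:
    """Genes x samples matrix with condition labels and spike-in flags.

    ``values`` is a pandas DataFrame (rows: gene ids, columns: sample ids) of
    finite nonnegative numbers; ``units`` records whether these are FPKM or
    counts; ``condition_of`` maps every sample to its condition label and
    ``is_spike`` flags ERCC-style spike-in rows.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]
    is_spike: pd.Series
    units: str = "FPKM"

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise ConfigError(f"samples without a condition label: {missing}")
        self.is_spike = self.is_spike.reindex(self.values.index).fillna(False).astype(bool)
        arr = self.values.to_numpy(dtype=float)
        if not (arr >= 0).all() or not pd.notna(arr).all() or not math.isfinite(arr.sum()):
            raise ParseError("expression values must be finite and nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def nonspike(self) -> pd.DataFrame:
        return self.values.loc[~self.is_spike]

    def spikes(self) -> pd.DataFrame:
        return self.values.loc[self.is_spike]

    def condition_means(self, condition: str) -> pd.Series:
        cols = self.samples_of(condition)
        if not cols:
            raise ConfigError(f"no samples with condition {condition!r}")
        return self.values[cols].mean(axis=1)

    def with_values(self, values: pd.DataFrame) -> "ExpressionTable":
        return ExpressionTable(
            values=values,
            condition_of=dict(self.condition_of),
            is_spike=self.is_spike.copy(),
            units=self.units,
        )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith(("#", "track", "browser"))


def read_bed(path: str, expect_strand: bool = False, strip_chr_prefix: bool = False):
    """Parse BED3/BED6 into Peak records, or ReadAlignment if ``expect_strand``.

    Records are returned in file order. Missing strand columns yield
    unstranded records unless ``expect_strand`` is set, in which case a
    ParseError is raised naming the offending line.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom = fields[0]
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else STRAND_NONE
            if strand not in _VALID_STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            if expect_strand:
                if strand == STRAND_NONE:
                    raise ParseError(
                        f"{path}:{lineno}: strand required but missing (BED3?)"
                    )
                records.append(
                    ReadAlignment(GenomicInterval(chrom, start, end, strand))
                )
            else:
                records.append(
                    Peak(GenomicInterval(chrom, start, end, strand), name=name, score=score)
                )
    return records


def write_bed(records: Iterable, path: str) -> None:
    """Write Peak or ReadAlignment records as BED6 (tab-separated)."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            if isinstance(rec, Peak):
                name = rec.name if rec.name is not None else "."
                score = "." if rec.score is None else format(rec.score, "g")
            else:
                name, score = ".", "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models: refFlat and GTF-lite
# ---------------------------------------------------------------------------

def _dedup_gene_models(raw: list[GeneModel]) -> list[GeneModel]:
    """One model per gene_id: duplicates resolved to the longest span."""
    by_id: dict[str, GeneModel] = {}
    for gm in raw:
        prev = by_id.get(gm.gene_id)
        if prev is None:
            by_id[gm.gene_id] = gm
        else:
            logger.warning(
                "duplicate gene_id %s: keeping longest span", gm.gene_id
            )
            if gm.interval.length > prev.interval.length:
                by_id[gm.gene_id] = gm
    return list(by_id.values())


def read_gene_models(path: str, dialect: str = "refFlat") -> list[GeneModel]:
    """Parse gene models from refFlat (0-based) or GTF-lite (1-based) text.

    GTF starts are shifted to the internal 0-based half-open convention.
    Duplicate gene ids keep the longest span with a logged warning.
    """
    if dialect not in ("refFlat", "gtf_lite"):
        raise ConfigError(f"unknown gene-model dialect {dialect!r}")
    raw: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if dialect == "refFlat":
                    # geneName name chrom strand txStart txEnd ...
                    if len(fields) < 6:
                        raise ValueError("expected >=6 refFlat fields")
                    gene_id, chrom, strand = fields[0], fields[2], fields[3]
                    start, end = int(fields[4]), int(fields[5])
                else:
                    if len(fields) < 9:
                        raise ValueError("expected 9 GTF fields")
                    chrom, strand = fields[0], fields[6]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    gene_id = _gtf_gene_id(fields[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in (STRAND_PLUS, STRAND_MINUS):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid span [{start}, {end})")
            raw.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand)))
    return _dedup_gene_models(raw)


def _gtf_gene_id(attributes: str) -> str:
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith("gene_id"):
            return chunk.split(None, 1)[1].strip().strip('"')
    raise ValueError("no gene_id attribute")


def write_gene_models(genes: Iterable[GeneModel], path: str, dialect: str = "refFlat") -> None:
    with open(path, "w") as fh:
        for gm in genes:
            iv = gm.interval
            if dialect == "refFlat":
                fh.write(
                    f"{gm.gene_id}\t{gm.gene_id}\t{iv.chrom}\t{iv.strand}\t{iv.start}\t{iv.end}"
                    f"\t{iv.start}\t{iv.end}\t1\t{iv.start},\t{iv.end},\n"
                )
            elif dialect == "gtf_lite":
                fh.write(
                    f"{iv.chrom}\tmycnload\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t."
                    f'\tgene_id "{gm.gene_id}";\n'
                )
            else:
                raise ConfigError(f"unknown gene-model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Expression matrix (TSV), half-life table, GMT
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str,
    condition_map: Mapping[str, str],
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    units: str = "FPKM",
) -> ExpressionTable:
    """Read a genes x samples TSV; rows whose id starts with ``spike_prefix``
    are flagged as spike-ins. Negative/non-numeric cells are parse errors."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~pd.Series(
            [math.isfinite(x) if pd.notna(x) else False for x in numeric], index=df.index
        )
        if bad.any():
            row = bad.idxmax()
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if (numeric < 0).any():
            row = numeric.idxmin()
            raise ParseError(f"{path}: negative value at row {row!r}, column {col!r}")
        df[col] = numeric
    is_spike = pd.Series(
        [str(g).startswith(spike_prefix) for g in df.index], index=df.index, dtype=bool
    )
    return ExpressionTable(
        values=df.astype(float),
        condition_of=dict(condition_map),
        is_spike=is_spike,
        units=units,
    )


def write_expression_table(table: ExpressionTable, path: str) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_halflife_table(path: str) -> pd.Series:
    """gene_id -> half-life (hours); values must be strictly positive."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    series = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if series.isna().any():
        bad = series.index[series.isna()][0]
        raise ParseError(f"{path}: non-numeric half-life for {bad!r}")
    if (series <= 0).any():
        bad = series.index[series <= 0][0]
        raise ParseError(f"{path}: non-positive half-life for {bad!r}")
    series.index = series.index.astype(str)
    return series.astype(float)


def write_halflife_table(halflives: pd.Series, path: str) -> None:
    halflives.rename("halflife_h").to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_gmt(path: str) -> dict[str, set[str]]:
    """GMT gene sets: name, description, members (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected name, description, members")
            name, members = fields[0], {m for m in fields[2:] if m}
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            member_list = sorted(set(members))
            fh.write(name + "\tna\t" + "\t".join(member_list) + "\n")
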