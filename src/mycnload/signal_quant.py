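"""Read-density quantification in rpm/bp and region area-under-curve.

Follows the bamliquidator convention: each aligned read is extended 3'-ward
by ``ext_bp`` (default 200 bp) and per-bp coverage is normalized to the total
number of million mapped reads, giving reads-per-million-per-bp (rpm/bp).
The cumulative signal over a region (rpm x bp) is the "load" currency used
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError
from .genomics_io import (
    STRAND_MINUS,
    STRAND_NONE,
    STRAND_PLUS,
    GenomicInterval,
    ReadAlignment,
)

logger = logging.getLogger(__name__)

DEFAULT_EXT_BP = 200


def extend_read(read: ReadAlignment, ext_bp: int = DEFAULT_EXT_BP) -> GenomicInterval:
    """3'-ward extension of a read by ``ext_bp``, clipped at position 0.

    The footprint length is read length + ext_bp before clipping: plus-strand
    reads grow rightward, minus-strand reads leftward.
    """
    iv = read.interval
    if ext_bp < 0:
        raise ConfigError("ext_bp must be nonnegative")
    if iv.strand == STRAND_PLUS:
        return GenomicInterval(iv.chrom, iv.start, iv.end + ext_bp, STRAND_PLUS)
    return GenomicInterval(iv.chrom, max(0, iv.start - ext_bp), iv.end, STRAND_MINUS)


@dataclass(frozen=True, slots=True)
class DensityResult:
    """Mean density (rpm/bp) and cumulative signal (rpm x bp) over a region."""

    region: GenomicInterval
    density: float
    auc: float


def region_density(
    reads: Iterable[ReadAlignment],
    region: GenomicInterval,
    total_mapped: int,
    ext_bp: int = DEFAULT_EXT_BP,
) -> DensityResult:
    """Mean extended-read base coverage over ``region``, depth-normalized.

    density = sum over reads of overlap(extended read, region)
              / region length / (total_mapped / 1e6)
    and auc = density * region length. Reads on other chromosomes contribute 0.
    """
    if total_mapped <= 0:
        raise ConfigError("total_mapped must be a positive integer")
    covered = 0
    for read in reads:
        covered += extend_read(read, ext_bp).overlap_bp(region)
    density = covered / region.length / (total_mapped / 1e6)
    return DensityResult(region=region, density=density, auc=density * region.length)


def _extend_arrays(starts, ends, strands, ext_bp):
    plus = strands == 1
    xs = np.where(plus, starts, np.maximum(0, starts - ext_bp))
    xe = np.where(plus, ends + ext_bp, ends)
    return xs, xe


class SignalTrack:
    """Piecewise-constant per-bp signal in rpm/bp, one piece list per chromosome.

    Stored as sorted breakpoints ``b`` and values ``v`` where ``v[i]`` holds on
    ``[b[i], b[i+1])``; positions outside covered pieces evaluate to 0. A
    cumulative-AUC array makes region queries O(log n).
    """

    def __init__(self, pieces: dict[str, tuple[np.ndarray, np.ndarray]], total_mapped: int):
        if total_mapped <= 0:
            raise ConfigError("total_mapped must be a positive integer")
        self.total_mapped = int(total_mapped)
        self._pieces: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (breaks, values) in pieces.items():
            breaks = np.asarray(breaks, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if len(breaks) != len(values) + 1:
                raise ValueError("need len(breaks) == len(values) + 1")
            if np.any(np.diff(breaks) <= 0):
                raise ValueError("breakpoints must be strictly increasing")
            if np.any(values < 0):
                raise ValueError("track values must be nonnegative")
            cum = np.concatenate([[0.0], np.cumsum(values * np.diff(breaks))])
            self._pieces[chrom] = (breaks, values, cum)

    @classmethod
    def from_reads(
        cls,
        reads: Sequence[ReadAlignment],
        total_mapped: int,
        ext_bp: int = DEFAULT_EXT_BP,
    ) -> "SignalTrack":
        """Pile up extended reads into an rpm/bp track (build_track)."""
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        n_unstranded = 0
        for read in reads:
            iv = read.interval
            strand = iv.strand
            if strand == STRAND_NONE:  # fail-soft: treat as + with a warning
                n_unstranded += 1
                strand = STRAND_PLUS
            by_chrom.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, 1 if strand == STRAND_PLUS else -1)
            )
        if n_unstranded:
            logger.warning("%d unstranded reads treated as + strand", n_unstranded)
        arrays = {
            chrom: tuple(np.array(col) for col in zip(*rows))
            for chrom, rows in by_chrom.items()
        }
        return cls.from_read_arrays(arrays, total_mapped, ext_bp)

    @classmethod
    def from_read_arrays(
        cls,
        arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_mapped: int,
        ext_bp: int = DEFAULT_EXT_BP,
    ) -> "SignalTrack":
        """Build from per-chromosome (starts, ends, strands) arrays.

        ``strands`` is +1 / -1. This avoids per-read Python objects for large
        simulated read sets.
        """
        if total_mapped <= 0:
            raise ConfigError("total_mapped must be a positive integer")
        scale = 1e6 / total_mapped
        pieces: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, strands) in arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            strands = np.asarray(strands)
            xs, xe = _extend_arrays(starts, ends, strands, ext_bp)
            pos = np.concatenate([xs, xe])
            delta = np.concatenate(
                [np.ones(len(xs), dtype=np.int64), -np.ones(len(xe), dtype=np.int64)]
            )
            breaks, inverse = np.unique(pos, return_inverse=True)
            net = np.bincount(inverse, weights=delta, minlength=len(breaks))
            counts = np.cumsum(net)[:-1]
            pieces[chrom] = (breaks, counts * scale)
        return cls(pieces, total_mapped)

    def chromosomes(self) -> list[str]:
        return sorted(self._pieces)

    def value_at(self, chrom: str, pos: int) -> float:
        piece = self._pieces.get(chrom)
        if piece is None:
            return 0.0
        breaks, values, _ = piece
        i = int(np.searchsorted(breaks, pos, side="right")) - 1
        if i < 0 or i >= len(values):
            return 0.0
        return float(values[i])

    def _cum_at(self, chrom: str, pos: int) -> float:
        breaks, values, cum = self._pieces[chrom]
        if pos <= breaks[0]:
            return 0.0
        if pos >= breaks[-1]:
            return float(cum[-1])
        i = int(np.searchsorted(breaks, pos, side="right")) - 1
        return float(cum[i] + values[i] * (pos - breaks[i]))

    def auc(self, region: GenomicInterval) -> float:
        """Cumulative signal (rpm x bp) over ``region``; 0 off-track."""
        if region.chrom not in self._pieces:
            return 0.0
        return self._cum_at(region.chrom, region.end) - self._cum_at(
            region.chrom, region.start
        )

    def mean_density(self, region: GenomicInterval) -> float:
        return self.auc(region) / region.length

    def iter_segments(self):
        """Yield (chrom, start, end, value) for every nonzero constant piece."""
        for chrom in self.chromosomes():
            breaks, values, _ = self._pieces[chrom]
            for i, v in enumerate(values):
                if v != 0.0:
                    yield chrom, int(breaks[i]), int(breaks[i + 1]), float(v)


def build_track(
    reads: Sequence[ReadAlignment],
    total_mapped: int,
    ext_bp: int = DEFAULT_EXT_BP,
) -> SignalTrack:
    """Precompute the rpm/bp pileup so many region queries are cheap."""
    return SignalTrack.from_reads(reads, total_mapped, ext_bp)


def track_auc(track: SignalTrack, region: GenomicInterval) -> float:
    """Cumulative area-under-curve signal over ``region`` (rpm x bp)."""
    return track.auc(region)


def write_bedgraph(track: SignalTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_bedgraph(path: str, total_mapped: int = 1_000_000) -> SignalTrack:
    """Load a bedGraph into a SignalTrack (values taken as already-normalized).

    Intervals must be disjoint; gaps become zero-valued pieces implicitly.
    """
    from .errors import ParseError

    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            fields = s.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph row") from exc
            rows.setdefault(fields[0], []).append((start, end, value))
    pieces: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, segs in rows.items():
        segs.sort()
        b: list[int] = [segs[0][0]]
        v: list[float] = []
        prev_end: int | None = None
        for start, end, value in segs:
            if prev_end is not None:
                if start < prev_end:
                    raise ParseError(f"{path}: overlapping bedGraph intervals on {chrom}")
                if start > prev_end:  # explicit zero piece over the gap
                    v.append(0.0)
                    b.append(start)
            v.append(value)
            b.append(end)
            prev_end = end
        pieces[chrom] = (np.array(b, dtype=np.int64), np.array(v, dtype=float))
    return SignalTrack(pieces, total_mapped)
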