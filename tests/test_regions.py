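"""Promoter/enhancer classification and per-gene load arithmetic."""

import numpy as np
import pytest

from mycnload.errors import ConfigError
from mycnload.genomics_io import GeneModel, GenomicInterval, Peak
from mycnload.regions import (
    LoadConfig,
    active_expressed_genes,
    classify_peaks,
    compute_loads,
    gene_load,
    promoter_window,
    tss_of,
)
from mycnload.signal_quant import SignalTrack

from conftest import make_expression


def gene(gid, start, end, strand, chrom="chr1"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


def peak(start, end, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end))


def constant_track(value, length=10_000_000, chrom="chr1"):
    return SignalTrack({chrom: (np.array([0, length]), np.array([float(value)]))}, 1)


class TestTssAndWindows:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [("+", 5000, 8000, 5000), ("-", 5000, 8000, 7999), ("-", 0, 1, 0)],
    )
    def test_tss_strand_convention(self, strand, start, end, expected):
        assert tss_of(gene("g", start, end, strand)) == expected

    def test_promoter_window_and_clipping(self):
        cfg = LoadConfig(promoter_halfwidth=1000)
        win = promoter_window(gene("g", 10_000, 20_000, "+"), cfg)
        assert (win.start, win.end) == (9000, 11_000)
        win = promoter_window(gene("g", 400, 900, "+"), cfg)
        assert (win.start, win.end) == (0, 1400)

    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            LoadConfig(promoter_halfwidth=0)
        with pytest.raises(ConfigError):
            LoadConfig(promoter_halfwidth=60_000, enhancer_halfwidth=50_000)


class TestClassifyPeaks:
    def test_promoter_and_enhancer_classes(self):
        g = gene("g", 10_000, 20_000, "+")  # window [9000, 11000)
        cls = classify_peaks([peak(9500, 9800), peak(30_000, 30_600)], [g])
        assert len(cls.promoter_peaks) == 1 and len(cls.enhancer_peaks) == 1
        assert cls.promoter_active["g"]
        assert cls.promoter_peak_genes[0] == frozenset({"g"})

    def test_half_open_boundary_is_enhancer(self):
        g = gene("g", 10_000, 20_000, "+")
        cls = classify_peaks([peak(11_000, 11_200)], [g])
        assert len(cls.enhancer_peaks) == 1
        assert not cls.promoter_active["g"]

    def test_partition_invariant_random(self, rng):
        genes = [
            gene(f"g{i}", int(p), int(p) + 5000, "+")
            for i, p in enumerate(np.sort(rng.integers(10_000, 900_000, 20)) * 10)
        ]
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, 9_500_000))
            peaks.append(peak(s, s + int(rng.integers(100, 3000))))
        cls = classify_peaks(peaks, genes)
        assert cls.n_peaks == len(peaks)
        prom_set = {(p.interval.start, p.interval.end) for p in cls.promoter_peaks}
        enh_set = {(p.interval.start, p.interval.end) for p in cls.enhancer_peaks}
        assert not (prom_set & enh_set)

    def test_peak_overlapping_two_windows_counts_for_both(self):
        ga = gene("ga", 10_000, 12_000, "+")  # window [9000, 11000)
        gb = gene("gb", 5_000, 10_500, "-")  # tss 10499, window [9499, 11499)
        cls = classify_peaks([peak(9600, 9700)], [ga, gb])
        assert cls.promoter_peak_genes[0] == frozenset({"ga", "gb"})


class TestGeneLoad:
    def test_promoter_rectangle(self):
        g = gene("g", 100_000, 120_000, "+")
        cls = classify_peaks([], [g])
        gl = gene_load(constant_track(2.0), g, cls)
        assert gl.promoter_load == pytest.approx(4000.0)
        assert gl.enhancer_load == 0.0

    def test_enhancer_peak_adds_area(self):
        g = gene("g", 100_000, 120_000, "+")
        tss = 100_000
        cls = classify_peaks([peak(tss + 5000, tss + 5500)], [g])
        gl = gene_load(constant_track(1.0), g, cls)
        assert gl.promoter_load == pytest.approx(2000.0)
        assert gl.enhancer_load == pytest.approx(500.0)
        assert gl.total_load == pytest.approx(2500.0)

    def test_enhancer_midpoint_outside_window_excluded(self):
        g = gene("g", 100_000, 120_000, "+")
        cls = classify_peaks([peak(100_000 + 59_800, 100_000 + 60_200)], [g])
        gl = gene_load(constant_track(1.0), g, cls)
        assert gl.enhancer_load == 0.0

    def test_promoter_bp_excluded_from_enhancer_peaks(self):
        # enhancer-class peak (of a neighbor) straddling this gene's window edge
        g = gene("g", 100_000, 120_000, "+")
        straddler = peak(100_500, 101_500)  # [tss+500, tss+1500); window ends tss+1000
        far = gene("far", 400_000, 420_000, "+")
        cls = classify_peaks([straddler], [far])  # promoter of nobody nearby
        assert len(cls.enhancer_peaks) == 1
        gl = gene_load(constant_track(1.0), g, cls)
        assert gl.enhancer_load == pytest.approx(500.0)  # only [101000, 101500)

    def test_enhancer_mode_window_uses_whole_span(self):
        g = gene("g", 100_000, 120_000, "+")
        cfg = LoadConfig(enhancer_mode="window")
        cls = classify_peaks([], [g])
        gl = gene_load(constant_track(1.0), g, cls, cfg)
        # 100 kb window minus the 2 kb promoter window
        assert gl.enhancer_load == pytest.approx(98_000.0)

    def test_compute_loads_matches_scalar_gene_load(self, rng):
        genes = [
            gene(f"g{i}", 200_000 * (i + 1), 200_000 * (i + 1) + 8000, s)
            for i, s in enumerate(rng.choice(["+", "-"], 8))
        ]
        peaks = []
        for g in genes:
            tss = tss_of(g)
            for _ in range(int(rng.integers(0, 4))):
                off = int(rng.integers(-48_000, 48_000))
                peaks.append(peak(tss + off, tss + off + int(rng.integers(200, 1500))))
        breaks = np.sort(rng.choice(np.arange(0, 3_000_000), 200, replace=False))
        values = rng.random(199) * 5
        track = SignalTrack({"chr1": (breaks, values)}, 1)
        cls = classify_peaks(peaks, genes)
        frame = compute_loads(track, genes, cls)
        for g in genes:
            gl = gene_load(track, g, cls)
            assert frame.at[g.gene_id, "promoter_load"] == pytest.approx(gl.promoter_load)
            assert frame.at[g.gene_id, "enhancer_load"] == pytest.approx(gl.enhancer_load)

    def test_monotone_in_track_and_shift_equivariant(self, rng):
        genes = [gene("g", 300_000, 308_000, "+")]
        pk = [peak(295_000, 296_000), peak(320_000, 321_000)]
        cls = classify_peaks(pk, genes)
        lo = gene_load(constant_track(1.0), genes[0], cls)
        hi = gene_load(constant_track(1.5), genes[0], cls)
        assert hi.promoter_load >= lo.promoter_load
        assert hi.enhancer_load >= lo.enhancer_load
        # shift everything by a constant
        shift = 12_345
        genes2 = [gene("g", 300_000 + shift, 308_000 + shift, "+")]
        pk2 = [
            peak(p.interval.start + shift, p.interval.end + shift) for p in pk
        ]
        cls2 = classify_peaks(pk2, genes2)
        shifted = gene_load(constant_track(1.0), genes2[0], cls2)
        assert shifted.promoter_load == pytest.approx(lo.promoter_load)
        assert shifted.enhancer_load == pytest.approx(lo.enhancer_load)


class TestActiveExpressed:
    def _cls(self, genes, active_ids):
        peaks = [
            peak(tss_of(g) - 50, tss_of(g) + 50)
            for g in genes
            if g.gene_id in active_ids
        ]
        return classify_peaks(peaks, genes)

    def test_top_half_intersection(self):
        genes = [gene(f"g{i}", 100_000 * (i + 1), 100_000 * (i + 1) + 5000, "+") for i in range(4)]
        genes = [gene(f"g{i+1}", 100_000 * (i + 1), 100_000 * (i + 1) + 5000, "+") for i in range(4)]
        cls = self._cls(genes, {"g1", "g2", "g3"})
        expr = make_expression(
            {"g1": [10, 10], "g2": [5, 5], "g3": [1, 1], "g4": [100, 100]},
            {"c1": "control", "c2": "control"},
        )
        assert active_expressed_genes(genes, cls, expr, "control") == {"g1"}

    def test_no_promoter_active_genes_gives_empty(self):
        genes = [gene("g1", 100_000, 105_000, "+")]
        cls = self._cls(genes, set())
        expr = make_expression({"g1": [10]}, {"c1": "control"})
        assert active_expressed_genes(genes, cls, expr, "control") == set()

    def test_all_equal_expression_keeps_all_active(self):
        genes = [gene(f"g{i}", 100_000 * (i + 1), 100_000 * (i + 1) + 5000, "+") for i in range(3)]
        cls = self._cls(genes, {g.gene_id for g in genes})
        expr = make_expression(
            {g.gene_id: [7.0] for g in genes}, {"c1": "control"}
        )
        assert active_expressed_genes(genes, cls, expr, "control") == {
            g.gene_id for g in genes
        }

    def test_missing_control_condition_errors(self):
        genes = [gene("g1", 100_000, 105_000, "+")]
        cls = self._cls(genes, {"g1"})
        expr = make_expression({"g1": [1.0]}, {"t1": "treated"})
        with pytest.raises(ConfigError):
            active_expressed_genes(genes, cls, expr, "control")
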