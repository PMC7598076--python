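# mycnload

Quantitative analysis linking MYCN chromatin occupancy ("MYCN load") to
drug-induced transcriptional response, for regulatory-genomics analyses of
MYCN-amplified neuroblastoma and similar amplifier-oncogene systems.

## The problem

Transcriptional CDK inhibitors cause a *global* knockdown of gene
expression whose depth varies gene by gene. Two measurement problems make
this hard to see with standard tooling:

1. **Occupancy must be turned into a per-gene scalar.** ChIP-seq reads are
   extended 200 bp toward their 3' end, piled up, and normalized to
   reads-per-million-per-bp (rpm/bp). A gene's *MYCN load* is the
   cumulative area under this signal over its promoter (±1 kb of the TSS)
   plus its enhancers — H3K27ac peaks outside any ±1 kb promoter window
   whose midpoints fall within ±50 kb of the TSS — in rpm·bp:

   `load(g) = AUC(track, TSS ± 1 kb) + Σ_peaks AUC(track, peak ∖ promoter)`

2. **A global amplitude shift is invisible after depth normalization.**
   ERCC spike-ins added in proportion to *cell number* provide an external
   anchor: per-sample size factors are the median across spikes of each
   spike's value over its geometric mean (rescaled to unit geometric
   mean), so a treatment that halves the whole transcriptome shows a
   median log2FC of −1 instead of ~0.

The core analysis ranks active, expressed genes (promoter H3K27ac peak and
top-50% control expression) by total load, takes the top 5000 into 5 bins
of 1000, and reports each bin's mean log2 fold change with a percentile
bootstrap 95% CI (10,000 resamples): response concordant with occupancy
appears as monotonically decreasing bin means. Around it sit the standard
expression-side procedures: differential-expression flagging (≥1.5-fold
and BH-FDR ≤ 0.1, Welch's t on log2(FPKM+1) replicates), mRNA half-life
stratification (<5 h vs >18 h, two-sided Wilcoxon rank-sum, exact by
enumeration at small n), signature scoring
(log2 of the ratio of set medians), and a minimal signal2noise + permutation
enrichment analysis.

A seeded synthetic-data module generates the complete input bundle — gene
models, H3K27ac/MYCN peaks and reads, expression tables with spikes,
half-lives, gene sets — with a *planted* load→response law
`log2FC(g) = log2(α) + β·z(load_g) + ε` and exports the ground truth, so
the entire pipeline is verifiable end to end without any downloads.

## Worked example

`python examples/02_load_and_response.py` simulates 800 genes with planted
slope β = −0.3 and amplitude α = 0.7, scores loads from the simulated
reads, and bins the active genes:

```
400 of 800 genes are promoter-active and in the top half of control expression
bin  mean_load  mean_log2fc        95% CI
  1    1164109       -0.875  [-0.998, -0.767]
  2     364494       -0.489  [-0.515, -0.463]
  3     191872       -0.457  [-0.483, -0.431]
  4      93349       -0.387  [-0.414, -0.361]
  5      31658       -0.343  [-0.372, -0.316]
```

Bin 1 (highest MYCN load) is the most repressed and the means rise
monotonically — the occupancy-concordant response the analysis is built to
detect. `python examples/03_spike_normalization.py` shows the spike-in
contrast under a pure 2× global knockdown:

```
spike-normalized median gene log2FC : -0.956
total-normalized median gene log2FC : -0.002
```

The other examples cover raw region density (rpm/bp) and the enrichment /
half-life procedures. A thin CLI wraps the same library:

```bash
mycnload simulate --out-dir data --seed 1
mycnload run --config config.json     # quantify → load → normalize → response → enrichment
```

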