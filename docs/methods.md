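# Methods

## Coordinate and signal conventions

All intervals are 0-based half-open. BED input is adopted verbatim; GTF
starts are shifted by −1 at parse time, so any refFlat/GTF pair describing
the same gene parses identically. Chromosome names are exact strings (an
opt-in flag strips a `chr` prefix); duplicate gene ids collapse to the
longest span with a logged warning — a deterministic, conservative choice
for the ±50 kb windows, since the underlying annotations do not say how
multi-isoform genes should be reduced to a single TSS.

Reads are extended **by** `ext_bp` (default 200 bp) toward the 3' end, so a
footprint is read length + 200 bp; footprints are clipped at position 0 but
not at chromosome ends (interval inputs carry no chromosome sizes — a
documented caveat, harmless for interior genes). Density over a region is
base-overlap of footprints divided by region length and by
`total_mapped/1e6`, giving rpm/bp; region AUC (rpm·bp) is density × length.
The `SignalTrack` stores the pileup as sorted breakpoints with a cumulative
AUC array, making each region query O(log n) and exactly equal (to 1e-9
relative) to the direct per-read computation.

## Load scoring

* Promoter window: `[TSS − 1 kb, TSS + 1 kb)`, TSS = start (+) or end − 1 (−).
* A H3K27ac peak is **promoter-class** iff it overlaps (≥1 bp) *any* gene's
  promoter window, else **enhancer-class**; the two classes partition the
  peak list. A peak overlapping two promoter windows is credited to both
  genes — the alternative (first-wins) would make results order-dependent.
* `promoter_load` = MYCN AUC over the promoter window. `enhancer_load` sums
  MYCN AUC over enhancer-class peaks whose midpoints lie within
  `[TSS − 50 kb, TSS + 50 kb)`, with promoter-window bp excised from the
  peak footprint so the two components are additive without double
  counting. An alternative `enhancer_mode="window"` takes raw AUC over the
  whole ±50 kb window (promoter excluded); the peak-restricted mode is the
  default because enhancers are *defined* as H3K27ac regions and raw-window
  AUC would absorb unannotated background.
* Active-expressed filter: promoter-active AND mean control expression at
  or above the 50th percentile (linear interpolation) of non-spike control
  means; the boundary is inclusive so ties at the median all qualify. The
  percentile is computed on control samples only, because the treatment
  globally depresses expression and the filter describes baseline activity.

## Ranked-bin response analysis

Genes are sorted by total load descending (ties by gene id, so the bin
boundary is stable across runs), truncated to the top 5000, and split into
5 contiguous bins; when the count is not divisible the remainder goes to the
highest-load bins. Per bin the mean load and mean log2FC are arithmetic
means; the CI is the 2.5th–97.5th percentile (linear interpolation) of
10,000 bootstrap resample means. Each bin draws a child seed from the
configured seed, so results do not depend on evaluation order and are
bit-reproducible. Percentile bootstrap (rather than BCa) is used because
only resampling-with-replacement is specified by the procedure being
implemented; its small-sample undercoverage (~93.5–94.5% at n = 50) is
within the calibration band the tests enforce.

## Differential expression

log2FC = log2((mean_T + ε)/(mean_C + ε)) with ε = 1 FPKM (configurable);
p-values from two-sided Welch's t on log2(value + ε) replicates; BH across
non-spike genes; both thresholds (1.5-fold, FDR 0.1) inclusive. The Welch +
BH combination is a deliberate, self-contained stand-in: the upstream
RNA-seq workflow this package consumes does not fix a DE model, and
moderated-variance models are out of scope. With fewer than 2 replicates in
a condition p is set to 1 with a warning rather than failing.

## Statistics

* **Wilcoxon rank-sum**: exact two-sided p by full enumeration of all
  C(n, nₐ) group assignments with midranks when min(n) ≤ 8 and total ≤ 20
  (bounding the enumeration at C(20,10) ≈ 1.8×10⁵); otherwise the normal
  approximation with tie and continuity corrections. Two-sided exact
  p = min(1, 2·min(tails)); all-tied inputs give p = 1. The method tag
  records which path ran.
* **Welch's t**: Satterthwaite df; both-groups-zero-variance returns p = 1
  (equal means) or 0 (unequal) as a documented convention.
* **BH**: step-up `q(i) = min_{j≥i} p(j)·m/j`, clipped at 1.
* **signal2noise**: (μ₁−μ₂)/(σ₁′+σ₂′) with σ′ = max(σ, 0.2·|μ|), or
  max(σ, 0.2) when μ = 0 (ddof = 1). The floor follows the reference GSEA
  implementation.
* **Enrichment score**: genes ranked by signal2noise descending (gene-id
  tiebreak); hits add |r|/Σ_set|r| (weight exponent 1), misses subtract
  1/(N−|set|); ES is the running-sum extremum, in [−1, 1]. Nominal
  p = (1 + #{|ES*| ≥ |ES|})/(n_perm + 1) with phenotype permutations when
  each condition has ≥ 4 samples, else same-size random gene sets; the mode
  is recorded in the result. No NES or cross-collection FDR is computed.
* **Tumor volume**: V = 4/3·π·((d₁+d₂)/4)³ mm³, symmetric in the two
  perpendicular caliper diameters.

## Spike-in normalization

Per-sample factor = median over usable spikes of (value / geometric mean of
that spike across samples), rescaled so factors have geometric mean 1;
normalized value = value / factor. Spikes with a zero anywhere are dropped
with a warning; fewer than two usable spikes is an error. One consequence of
the unit-geometric-mean constraint: multiplying one of S samples by c shifts
*all* normalized values by the common constant c^(1/S) while every
between-sample ratio — the quantity the analysis consumes — is exactly
invariant. `total_size_factors` (library-size style, non-spike totals)
is provided as the deliberately blind contrast.

## Synthetic data: what it emulates and what it does not

The generator plants `log2FC(g) = log2(α) + β·z(λ_g) + ε_g` with
λ ~ lognormal(μ=5, s=1.2) (heavy-tailed occupancy), β = −0.3 per standard
deviation of load, ε ~ N(0, σ=0.1), and α = 0.7 (a 30% global knockdown);
3 replicates per condition, 20 ERCC spikes whose expected values are equal
in every sample (cell-number anchoring — α applies to genes only), and
half-lives log-normal around 9 h with a −0.6 coefficient on z(λ), so
high-load genes are short-lived. Replicate noise is multiplicative
2^N(0, σ) using the same σ, so σ = 0 produces exactly deterministic tables.
Defaults (5000 genes on a 100 Mb chromosome, 0.5 reads per rpm·bp unit of
load, 0.01 background reads/kb, 50 bp reads) keep a full run at desk scale
(seconds) while giving stable recovery of the planted structure.

Genes occupy a jittered grid: equal slots with random in-slot placement.
At low density (≤ ~900 genes on 100 Mb) neighboring ±50 kb windows stay
disjoint and computed load tracks planted load with r > 0.95; at the
5000-gene default, window overlap — and hence peak crosstalk between
neighbors, which real genomes also exhibit — is present by construction.
Reads are placed so the 3'-extended footprint stays inside the generating
peak, making each signal read contribute its full footprint to the load.

Not emulated: fragment-length and GC biases, genome sequence, multi-isoform
structure, peak-caller noise (peaks are generated, not called), batch
effects, and count-level mean–variance relationships. Passing recovery
tests therefore demonstrates the *pipeline arithmetic* end to end — not
robustness to those real-data pathologies.

## Pipeline determinism

A single JSON/YAML config drives quantify → load → normalize → DE →
ranked-bin response → half-life test → signatures/enrichment. Every output
TSV carries `# key=value` header lines naming its parameters; the manifest
stores stage outputs relative to the output directory; all floats are
written with `%.10g`. Two runs with the same config and seed are
byte-identical. Validation failures (missing files, bad thresholds) abort
before any output is written; exit codes distinguish validation (2) from
data (3) errors in the CLI.

## Known limitations

* Enhancer attribution is purely positional (±50 kb midpoint rule); no
  contact maps, no superenhancer stitching.
* DE p-values assume approximate log-normality of replicate FPKM; with 2–3
  replicates the Welch test is underpowered, which the inclusive FDR ≤ 0.1
  threshold only partly offsets.
* The exact Wilcoxon path is capped at 20 total observations; beyond that
  the tie-corrected normal approximation is used even when min(n) ≤ 8.
* Spike normalization assumes spike counts are proportional to cell number
  with the same capture efficiency across samples; systematic spike capture
  drift would be misread as a transcriptome amplitude change.
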