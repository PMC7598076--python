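"""Recover a planted MYCN-load -> transcriptional-response relationship.

Simulates a small genome with heavy-tailed MYCN occupancy and an expression
response whose log2 fold change decreases with standardized load
(slope beta = -0.3) on top of a global 0.7x amplitude shift. The pipeline
then classifies H3K27ac peaks, scores per-gene promoter + enhancer load,
keeps active highly-expressed genes, ranks them by load into 5 bins, and
reports each bin's mean response with a bootstrap 95% CI.
"""

from mycnload import (
    BinConfig,
    SignalTrack,
    active_expressed_genes,
    bin_response,
    classify_peaks,
    compute_loads,
    log2fc_map,
    rank_and_bin,
)
from mycnload.simulate import simulate_dataset

ds = simulate_dataset(n_genes=800, seed=42)  # beta=-0.3, alpha=0.7, sigma=0.1

track = SignalTrack.from_read_arrays(ds.chip.read_arrays, ds.chip.total_mapped)
classification = classify_peaks(ds.chip.peaks, ds.genes)
loads = compute_loads(track, ds.genes, classification)
active = active_expressed_genes(ds.genes, classification, ds.expression, "control")
print(f"{len(active)} of {len(ds.genes)} genes are promoter-active and in the "
      "top half of control expression")

cfg = BinConfig(n_top=5000, n_bins=5, bootstrap_iters=2000, seed=42)
active_loads = loads.loc[sorted(active)]
bins = rank_and_bin(active_loads, cfg)
fc = log2fc_map(ds.expression, "treated", "control")
print("bin  mean_load  mean_log2fc        95% CI")
for s in bin_response(bins, fc, active_loads, cfg):
    print(f"{s.bin_index:>3}  {s.mean_load:>9.0f}  {s.mean_log2fc:>11.3f}  "
          f"[{s.ci_low:.3f}, {s.ci_high:.3f}]")

# Bin 1 holds the most MYCN-loaded genes; its mean log2FC is the most
# negative, and the means rise monotonically toward bin 5 - the planted
# concordance between occupancy and drug response.
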