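"""End-to-end orchestration: quantify -> load -> normalize -> response -> enrichment.

A single config (JSON or YAML) names every input file and parameter; the
run writes one TSV per stage plus a JSON manifest and is byte-identical
across reruns with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomics_io as gio
from .errors import ConfigError, DataError
from .normalize import (
    apply_size_factors,
    gsea_lite,
    signature_comparison,
    signature_score,
    spike_size_factors,
)
from .regions import LoadConfig, active_expressed_genes, classify_peaks, compute_loads
from .response import (
    BinConfig,
    DEConfig,
    bin_response,
    de_classify,
    halflife_strata,
    log2fc_map,
    rank_and_bin,
)
from .signal_quant import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths plus every stage parameter, with the reference defaults."""

    reads_bed: str
    peaks_bed: str
    genes_path: str
    expression_tsv: str
    out_dir: str
    total_mapped: int
    halflife_tsv: str | None = None
    gmt_path: str | None = None
    genes_dialect: str = "refFlat"
    spike_prefix: str = gio.DEFAULT_SPIKE_PREFIX
    treated: str = "treated"
    control: str = "control"
    conditions: dict[str, str] | None = None  # sample -> condition; inferred if None
    use_normalized_log2fc: bool = True
    seed: int = 0
    n_perm: int = 1000
    load: LoadConfig = field(default_factory=LoadConfig)
    bins: BinConfig = field(default_factory=BinConfig)
    de: DEConfig = field(default_factory=DEConfig)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        load_cfg = LoadConfig(**raw.pop("load", {}))
        bin_kwargs = raw.pop("bins", {})
        de_cfg = DEConfig(**raw.pop("de", {}))
        known = {f for f in cls.__dataclass_fields__ if f not in ("load", "bins", "de")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(load=load_cfg, bins=BinConfig(**bin_kwargs), de=de_cfg, **raw)
        return cfg

    def validate(self) -> None:
        required = {
            "reads_bed": self.reads_bed,
            "peaks_bed": self.peaks_bed,
            "genes_path": self.genes_path,
            "expression_tsv": self.expression_tsv,
        }
        optional = {"halflife_tsv": self.halflife_tsv, "gmt_path": self.gmt_path}
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise ConfigError(f"{name}: file not found: {path}")
        if self.total_mapped <= 0:
            raise ConfigError("total_mapped must be positive")


def _infer_conditions(sample_ids, treated: str, control: str) -> dict[str, str]:
    """Map sample "control_1" -> "control" by stripping a trailing _<n>."""
    out = {}
    for s in sample_ids:
        base = s.rsplit("_", 1)[0]
        if base not in (treated, control):
            raise ConfigError(
                f"cannot infer condition for sample {s!r}; provide a conditions map"
            )
        out[s] = base
    return out


def _write_tsv(df: pd.DataFrame, path: Path, params: dict, index_label: str) -> None:
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"# {key}={params[key]}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Outputs (under cfg.out_dir): loads.tsv, size_factors.tsv,
    normalized_expression.tsv, de.tsv, bins.tsv, halflife_test.json,
    signatures.tsv (if a GMT is given), gsea.tsv, manifest.json.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "warnings": [], "seed": cfg.seed}

    def stage(name: str, outputs: list, **info) -> None:
        # paths are stored relative to out_dir so a rerun elsewhere is comparable
        rel = [str(Path(o).name) for o in outputs]
        manifest["stages"].append({"name": name, "outputs": rel, **info})

    # --- inputs -----------------------------------------------------------
    reads = gio.read_bed(cfg.reads_bed, expect_strand=True)
    peaks = gio.read_bed(cfg.peaks_bed)
    genes = gio.read_gene_models(cfg.genes_path, dialect=cfg.genes_dialect)
    header = pd.read_csv(cfg.expression_tsv, sep="\t", nrows=0, comment="#")
    sample_ids = [str(c) for c in header.columns[1:]]
    conditions = cfg.conditions or _infer_conditions(sample_ids, cfg.treated, cfg.control)
    expr = gio.read_expression_table(
        cfg.expression_tsv, condition_map=conditions, spike_prefix=cfg.spike_prefix
    )

    # --- quantify + load --------------------------------------------------
    track = SignalTrack.from_reads(reads, cfg.total_mapped, ext_bp=cfg.load.ext_bp)
    classification = classify_peaks(peaks, genes, cfg.load)
    loads = compute_loads(track, genes, classification, cfg.load)
    loads_path = out / "loads.tsv"
    _write_tsv(
        loads,
        loads_path,
        {
            "promoter_halfwidth": cfg.load.promoter_halfwidth,
            "enhancer_halfwidth": cfg.load.enhancer_halfwidth,
            "ext_bp": cfg.load.ext_bp,
            "enhancer_mode": cfg.load.enhancer_mode,
            "total_mapped": cfg.total_mapped,
        },
        index_label="gene_id",
    )
    stage("load", [str(loads_path)], n_genes=len(genes), n_peaks=len(peaks))

    # --- normalize --------------------------------------------------------
    factors = spike_size_factors(expr)
    normalized = apply_size_factors(expr, factors)
    sf_path = out / "size_factors.tsv"
    _write_tsv(
        factors.factors.rename("size_factor").to_frame(),
        sf_path,
        {"method": factors.method, "spike_prefix": cfg.spike_prefix},
        index_label="sample_id",
    )
    norm_path = out / "normalized_expression.tsv"
    _write_tsv(normalized.values, norm_path, {"normalization": factors.method}, "gene_id")
    stage("normalize", [str(sf_path), str(norm_path)], method=factors.method)

    # --- differential expression -----------------------------------------
    expr_for_fc = normalized if cfg.use_normalized_log2fc else expr
    de = de_classify(expr_for_fc, cfg.treated, cfg.control, cfg.de)
    de_path = out / "de.tsv"
    _write_tsv(
        de.table,
        de_path,
        {
            "fold_threshold": cfg.de.fold_threshold,
            "fdr_threshold": cfg.de.fdr_threshold,
            "pseudocount": cfg.de.pseudocount,
            "treated": cfg.treated,
            "control": cfg.control,
            "normalized": cfg.use_normalized_log2fc,
        },
        index_label="gene_id",
    )
    stage(
        "de",
        [str(de_path)],
        n_up=de.n_up,
        n_down=de.n_down,
        down_up_ratio=de.down_up_ratio if np.isfinite(de.down_up_ratio) else None,
    )

    # --- rank, bin, bootstrap --------------------------------------------
    active = active_expressed_genes(genes, classification, expr_for_fc, cfg.control)
    if len(active) < cfg.bins.n_bins:
        raise DataError(
            f"only {len(active)} active-expressed genes; cannot form {cfg.bins.n_bins} bins"
        )
    fc = log2fc_map(expr_for_fc, cfg.treated, cfg.control, cfg.de.pseudocount)
    active_loads = loads.loc[sorted(active)]
    bins = rank_and_bin(active_loads, cfg.bins)
    summaries = bin_response(bins, fc, active_loads, cfg.bins)
    bins_df = pd.DataFrame(
        [
            {
                "bin": s.bin_index,
                "n_genes": len(s.gene_ids),
                "mean_load": s.mean_load,
                "mean_log2fc": s.mean_log2fc,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
            for s in summaries
        ]
    ).set_index("bin")
    bins_path = out / "bins.tsv"
    _write_tsv(
        bins_df,
        bins_path,
        {
            "n_top": cfg.bins.n_top,
            "n_bins": cfg.bins.n_bins,
            "bootstrap_iters": cfg.bins.bootstrap_iters,
            "ci_level": cfg.bins.ci_level,
            "seed": cfg.bins.seed,
            "n_active_expressed": len(active),
        },
        index_label="bin",
    )
    stage("response", [str(bins_path)], n_active_expressed=len(active))

    # --- half-life strata -------------------------------------------------
    outputs_hl: list[str] = []
    if cfg.halflife_tsv:
        halflives = gio.read_halflife_table(cfg.halflife_tsv)
        strata = halflife_strata(fc, halflives)
        hl_path = out / "halflife_test.json"
        with open(hl_path, "w") as fh:
            json.dump(
                {
                    "short_threshold_h": strata.short_threshold_h,
                    "long_threshold_h": strata.long_threshold_h,
                    "n_short": int(strata.short_log2fc.size),
                    "n_long": int(strata.long_log2fc.size),
                    "median_short_log2fc": float(np.median(strata.short_log2fc))
                    if strata.short_log2fc.size
                    else None,
                    "median_long_log2fc": float(np.median(strata.long_log2fc))
                    if strata.long_log2fc.size
                    else None,
                    "p_value": strata.p_value,
                    "method": strata.method,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        outputs_hl.append(str(hl_path))
        stage("halflife", outputs_hl, p_value=strata.p_value)

    # --- signatures + enrichment -----------------------------------------
    if cfg.gmt_path:
        sets = gio.read_gmt(cfg.gmt_path)
        scores = [
            signature_score(normalized, members, cfg.treated, cfg.control, set_name=name)
            for name, members in sets.items()
        ]
        sig_df = pd.DataFrame(
            [
                {
                    "set_name": s.set_name,
                    "score_log2fc_of_medians": s.score,
                    "median_gene_log2fc": float(s.gene_log2fc.median()),
                    "n_members_used": s.n_members_used,
                    "n_members_missing": s.n_members_missing,
                }
                for s in scores
            ]
        ).set_index("set_name")
        sig_path = out / "signatures.tsv"
        _write_tsv(sig_df, sig_path, {"treated": cfg.treated, "control": cfg.control}, "set_name")
        pairs = signature_comparison(scores)
        pairs_path = out / "signature_comparisons.tsv"
        if pairs.empty:
            pairs_path.write_text("# no signature pairs\n")
        else:
            _write_tsv(pairs.set_index(["set_a", "set_b"]), pairs_path, {}, "set_a")
        rng = np.random.default_rng(cfg.seed)
        gsea_rows = []
        for name, members in sets.items():
            res = gsea_lite(
                normalized,
                cfg.treated,
                cfg.control,
                members,
                set_name=name,
                n_perm=cfg.n_perm,
                seed=int(rng.integers(0, 2**31)),
            )
            gsea_rows.append(
                {
                    "set_name": res.set_name,
                    "es": res.es,
                    "nominal_p": res.nominal_p,
                    "n_perm": res.n_perm,
                    "perm_mode": res.perm_mode,
                    "set_size": res.set_size,
                }
            )
        gsea_df = pd.DataFrame(gsea_rows).set_index("set_name")
        gsea_path = out / "gsea.tsv"
        _write_tsv(gsea_df, gsea_path, {"n_perm": cfg.n_perm, "seed": cfg.seed}, "set_name")
        stage("enrichment", [str(sig_path), str(pairs_path), str(gsea_path)])

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest
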