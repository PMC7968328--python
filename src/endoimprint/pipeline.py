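"""End-to-end orchestration: simulate -> screen -> count -> call -> context.

A single YAML run config drives every stage; each output table carries a
commented header with the tool version and config hash, and a manifest
plus a human-readable summary report are written at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__, alleles, calling, context, io, simulate, snps
from .config import (Design, ImprintThresholds, SimConfig, config_hash,
                     sim_config_from_dict)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    sim: Optional[SimConfig] = None
    inputs: dict = field(default_factory=dict)
    thresholds: ImprintThresholds = field(default_factory=ImprintThresholds)
    cluster_window: int = 1_000_000
    cluster_step: int = 100_000
    cluster_alpha: float = 0.05
    te_flank: int = 5000
    min_snp_depth: int = 10
    min_snp_replicates: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = None
        if "simulate" in d and d["simulate"] is not None:
            sim_d = dict(d["simulate"])
            sim_d.setdefault("seed", d.get("seed", 0))
            sim = sim_config_from_dict(sim_d)
        thr = ImprintThresholds(**d.get("thresholds", {}))
        cluster = d.get("cluster", {})
        return cls(
            out_dir=Path(d.get("out", "endoimprint_run")),
            sim=sim,
            inputs=d.get("inputs", {}),
            thresholds=thr,
            cluster_window=int(cluster.get("window", 1_000_000)),
            cluster_step=int(cluster.get("step", 100_000)),
            cluster_alpha=float(cluster.get("alpha", 0.05)),
            te_flank=int(d.get("te_flank", 5000)),
            min_snp_depth=int(d.get("min_snp_depth", 10)),
            min_snp_replicates=int(d.get("min_snp_replicates", 2)),
            seed=int(d.get("seed", 0)),
        )

    def validate_inputs(self) -> None:
        if self.sim is not None:
            return
        required = ("genes_gff3", "parent_vcfs", "allele_depths", "design")
        for key in required:
            if key not in self.inputs:
                raise FileNotFoundError(f"run config missing input {key!r}")
        paths = [self.inputs["genes_gff3"], self.inputs["allele_depths"],
                 self.inputs["design"]]
        for line_vcfs in self.inputs["parent_vcfs"].values():
            paths.extend(line_vcfs.values())
        for opt in ("te_bed", "expression"):
            if opt in self.inputs:
                paths.append(self.inputs[opt])
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_inputs()
    meta = {"config_hash": config_hash({
        "thresholds": config.thresholds.__dict__,
        "sim": config.sim.__dict__ if config.sim else None,
        "cluster": [config.cluster_window, config.cluster_step,
                    config.cluster_alpha],
        "te_flank": config.te_flank, "seed": config.seed,
    }), "version": __version__}
    manifest: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    # -- simulate -----------------------------------------------------------
    if config.sim is not None:
        _stage("simulate")
        sim_manifest = simulate.write_bundle(config.sim, out / "sim")
        manifest.update({f"sim_{k}": v for k, v in sim_manifest.items()})
        lines = (config.sim.line1, config.sim.line2)
        inputs = {
            "genes_gff3": sim_manifest["genes_gff3"],
            "parent_vcfs": {
                line: {rep: sim_manifest[f"vcf_{line}_rep{rep}"]
                       for rep in range(1, config.sim.n_replicates + 1)}
                for line in lines},
            "allele_depths": sim_manifest["allele_depths_tsv"],
            "design": sim_manifest["design_yaml"],
            "te_bed": sim_manifest["te_bed"],
            "expression": sim_manifest["expression_tsv"],
        }
    else:
        inputs = config.inputs

    design = Design.from_yaml(inputs["design"])
    line1, line2 = design.lines
    gene_models = io.read_gene_models(inputs["genes_gff3"])

    # -- diagnostic SNP screen ---------------------------------------------
    _stage("snps")
    vcfs = inputs["parent_vcfs"]
    diagnostic = snps.screen_vcf_files(
        {str(r): p for r, p in vcfs[line1].items()},
        {str(r): p for r, p in vcfs[line2].items()},
        line1, line2, min_depth=config.min_snp_depth,
        min_replicates=config.min_snp_replicates)
    diagnostic = snps.map_snps_to_genes(diagnostic, gene_models)
    snp_df = snps.snps_to_frame(diagnostic)
    io.write_tsv(snp_df, out / "diagnostic_snps.tsv", meta)
    manifest["diagnostic_snps"] = str(out / "diagnostic_snps.tsv")

    # -- allele counting ----------------------------------------------------
    _stage("count")
    depths = alleles.load_allele_depths_from_table(inputs["allele_depths"])
    genic = snp_df.dropna(subset=["gene_id"])
    keep = depths.merge(genic[["chrom", "pos"]].drop_duplicates(),
                        on=["chrom", "pos"], how="inner")
    oriented = alleles.orient_counts_by_cross(keep, design)
    gene_counts = alleles.aggregate_gene_counts(
        oriented.drop(columns=["gene_id"], errors="ignore"),
        snp_gene_map=genic)
    io.write_tsv(gene_counts, out / "gene_allele_counts.tsv", meta)
    manifest["gene_allele_counts"] = str(out / "gene_allele_counts.tsv")

    # -- imprint calling ----------------------------------------------------
    _stage("call")
    calls_by_stage: dict[str, pd.DataFrame] = {}
    for stage in design.stages:
        calls = calling.call_imprinted_genes(gene_counts, config.thresholds,
                                             stage=stage)
        calls_by_stage[stage] = calls
        path = out / f"imprint_calls_{stage}.tsv"
        io.write_tsv(calls, path, meta)
        manifest[f"imprint_calls_{stage}"] = str(path)

    stages = list(design.stages)
    results: dict = {"stages": stages}
    if len(stages) >= 2:
        overlap = calling.summarize_stage_overlap(calls_by_stage[stages[0]],
                                                  calls_by_stage[stages[1]])
        io.write_tsv(overlap, out / "stage_overlap.tsv", meta)
        manifest["stage_overlap"] = str(out / "stage_overlap.tsv")
        comparison = calling.compare_stages(calls_by_stage[stages[0]],
                                            calls_by_stage[stages[1]])
        io.write_tsv(comparison, out / "stage_comparison.tsv", meta)
        manifest["stage_comparison"] = str(out / "stage_comparison.tsv")
        results["overlap"] = overlap
        results["comparison"] = comparison

    union_imprinted = sorted(set().union(*[
        set(c.loc[c["class"].isin(calling.IMPRINTED_CLASSES), "gene_id"])
        for c in calls_by_stage.values()]))
    results["imprinted_union"] = union_imprinted
    # the summary only needs membership, so any imprinted class label works
    sub_summary = calling.subgenome_bias_summary(
        pd.DataFrame({"gene_id": union_imprinted,
                      "class": ["MEG"] * len(union_imprinted)}),
        gene_models)
    with open(out / "subgenome_summary.json", "w") as fh:
        json.dump({k: v for k, v in sub_summary.items() if k != "pairs"},
                  fh, indent=2)
    manifest["subgenome_summary"] = str(out / "subgenome_summary.json")
    results["subgenome"] = sub_summary

    # -- clusters -----------------------------------------------------------
    _stage("clusters")
    windows, clusters = context.detect_clusters(
        union_imprinted, gene_models, window=config.cluster_window,
        step=config.cluster_step, alpha=config.cluster_alpha)
    io.write_tsv(windows, out / "windows.tsv", meta)
    io.write_tsv(clusters, out / "clusters.tsv", meta)
    manifest["windows"] = str(out / "windows.tsv")
    manifest["clusters"] = str(out / "clusters.tsv")
    results["clusters"] = clusters

    # -- TE enrichment ------------------------------------------------------
    if "te_bed" in inputs:
        _stage("te-enrich")
        tes = io.read_te_bed(inputs["te_bed"])
        te_rows = context.te_flank_enrichment(gene_models, union_imprinted,
                                              tes, flank=config.te_flank)
        io.write_tsv(te_rows, out / "te_enrichment.tsv", meta)
        manifest["te_enrichment"] = str(out / "te_enrichment.tsv")
        results["te_enrichment"] = te_rows

    # -- expression ---------------------------------------------------------
    if "expression" in inputs:
        _stage("expression")
        expr = io.read_tsv(inputs["expression"])
        profiles = context.classify_tissue_specificity(expr)
        io.write_tsv(profiles, out / "tissue_specificity.tsv", meta)
        manifest["tissue_specificity"] = str(out / "tissue_specificity.tsv")
        results["tissue_specificity"] = profiles
        if len(union_imprinted) >= 2:
            results["expression_test"] = \
                context.compare_expression_imprinted_vs_not(
                    expr, union_imprinted)

    # -- report -------------------------------------------------------------
    report = write_reports(results, snp_df, calls_by_stage,
                           out / "report.txt")
    manifest["report"] = str(out / "report.txt")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest"] = str(out / "manifest.json")
    return manifest


def write_reports(results: dict, snp_df: pd.DataFrame,
                  calls_by_stage: dict[str, pd.DataFrame],
                  path) -> str:
    """Render the one-page summary report (idempotent for fixed inputs)."""
    lines = ["endoimprint run summary", "=" * 40]
    n_snps = len(snp_df)
    n_genic = int(snp_df["gene_id"].notna().sum()) if n_snps else 0
    lines.append(f"diagnostic SNP records retained: {n_snps} "
                 f"({n_genic} inside genes)")
    for stage, calls in calls_by_stage.items():
        counts = calls["class"].value_counts()
        lines.append(
            f"stage {stage}: {len(calls)} genes tested | "
            f"MEG {counts.get('MEG', 0)}, PEG {counts.get('PEG', 0)}, "
            f"biallelic {counts.get('biallelic', 0)}, "
            f"insufficient {counts.get('insufficient', 0)}")
    if "overlap" in results:
        total = results["overlap"]
        row = total[total["class"] == "imprinted"].iloc[0]
        lines.append(f"stage overlap: union {row['union']}, "
                     f"intersection {row['n_both']}")
    if "subgenome" in results:
        s = results["subgenome"]
        lines.append(f"subgenome split (unpaired): A {s['unpaired_A']} "
                     f"({s['pct_A']}%), C {s['unpaired_C']} ({s['pct_C']}%)"
                     f"; homolog pairs both imprinted: "
                     f"{s['n_pairs_both_imprinted']}")
    if "clusters" in results:
        cl = results["clusters"]
        lines.append(f"imprinting clusters: {len(cl)} "
                     f"({int(cl['n_members'].sum()) if len(cl) else 0} "
                     f"clustered genes)")
    if "te_enrichment" in results:
        te = results["te_enrichment"]
        sig = te[(te["p"] < 0.05) & (te["te_family"] != "all")]
        top = sig.sort_values("p").head(3)
        desc = "; ".join(f"{r.te_family} {r.region} p={r.p:.2g}"
                         for r in top.itertuples(index=False)) or "none"
        lines.append(f"top TE flank enrichments: {desc}")
    if "tissue_specificity" in results:
        prof = results["tissue_specificity"]
        lines.append(f"endosperm-specific genes: "
                     f"{int(prof['endosperm_specific'].sum())}")
    if "expression_test" in results:
        e = results["expression_test"]
        lines.append(f"imprinted vs non-imprinted endosperm expression: "
                     f"t={e['t']:.3f}, p={e['p']:.3g} {e['stars']}")
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return text
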