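"""Validation experiments: recovery of simulated truth and null calibration.

These run the full generator -> orient -> aggregate -> call chain on
configurations with known ground truth and measure sensitivity, false
discovery and null rejection rates.  They back the package's operating
characteristics quoted in the docs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .alleles import aggregate_gene_counts, orient_counts_by_cross
from .calling import IMPRINTED_CLASSES, call_imprinted_genes
from .config import Design, ImprintThresholds, SimConfig
from .context import detect_clusters


def _recovery_config(seed: int, n_biallelic: int, n_meg: int, n_peg: int,
                     depth: float, rho: float) -> SimConfig:
    n = n_biallelic + n_meg + n_peg
    per_chrom = -(-n // 10)  # ceil; 5 A + 5 C chromosomes
    n_total = 10 * per_chrom
    return SimConfig(
        seed=seed, n_chrom_a=5, n_chrom_c=5,
        genes_per_chrom=per_chrom,
        chrom_length=max(6_000_000, per_chrom * 5000),
        snps_per_gene=1.0, depth_mean=depth, overdispersion=rho,
        frac_meg=n_meg / n_total,
        frac_peg=n_peg / n_total,
        stages=("20DAP",), stage_switch_frac=0.0, corrupt_frac=0.0,
        cluster_frac=0.0)


def recovery_metrics(seed: int, n_biallelic: int = 5000, n_meg: int = 500,
                     n_peg: int = 50, depth: float = 60.0,
                     rho: float = 0.0,
                     thresholds: ImprintThresholds = ImprintThresholds()
                     ) -> dict:
    """Simulate one stage of the reciprocal design and score the calls
    against truth.  Returns per-class sensitivity, the false-discovery
    fraction among called genes, and the null (biallelic) call rate."""
    cfg = _recovery_config(seed, n_biallelic, n_meg, n_peg, depth, rho)
    genes = simulate.simulate_gene_annotation(cfg)
    truth = simulate.assign_truth(cfg, genes)
    snps = simulate.simulate_parental_variants(cfg, genes)
    depths = simulate.simulate_hybrid_allele_depths(cfg, truth, snps)
    design = Design.from_sim_config(cfg)
    oriented = orient_counts_by_cross(depths, design)
    gene_counts = aggregate_gene_counts(oriented)
    calls = call_imprinted_genes(gene_counts, thresholds,
                                 stage=cfg.stages[0])
    merged = calls.merge(truth[["gene_id", "true_class"]], on="gene_id")

    def _sens(klass):
        true = merged["true_class"] == klass
        return float((true & (merged["class"] == klass)).sum()
                     / max(int(true.sum()), 1))

    called = merged["class"].isin(IMPRINTED_CLASSES)
    truly = merged["true_class"].isin(IMPRINTED_CLASSES)
    biallelic = merged["true_class"] == "biallelic"
    return {
        "n_genes": len(merged),
        "n_true_meg": int((merged["true_class"] == "MEG").sum()),
        "n_true_peg": int((merged["true_class"] == "PEG").sum()),
        "n_true_biallelic": int(biallelic.sum()),
        "tp_meg": int(((merged["true_class"] == "MEG")
                       & (merged["class"] == "MEG")).sum()),
        "tp_peg": int(((merged["true_class"] == "PEG")
                       & (merged["class"] == "PEG")).sum()),
        "false_calls": int((called & ~truly).sum()),
        "n_called": int(called.sum()),
        "meg_sensitivity": _sens("MEG"),
        "peg_sensitivity": _sens("PEG"),
        "false_discovery": float((called & ~truly).sum()
                                 / max(int(called.sum()), 1)),
        "null_call_rate": float((called & biallelic).sum()
                                / max(int(biallelic.sum()), 1)),
    }


def pooled_recovery(seeds, **kwargs) -> dict:
    """Recovery metrics pooled over several seeds (counts summed)."""
    keys = ("n_true_meg", "n_true_peg", "n_true_biallelic", "tp_meg",
            "tp_peg", "false_calls", "n_called")
    tot = dict.fromkeys(keys, 0)
    seeds = list(seeds)
    for seed in seeds:
        m = recovery_metrics(seed, **kwargs)
        for k in keys:
            tot[k] += m[k]
    return {
        "meg_sensitivity": tot["tp_meg"] / max(tot["n_true_meg"], 1),
        "peg_sensitivity": tot["tp_peg"] / max(tot["n_true_peg"], 1),
        "false_discovery": tot["false_calls"] / max(tot["n_called"], 1),
        "null_call_rate": tot["false_calls"]
        / max(tot["n_true_biallelic"], 1),
        "n_seeds": len(seeds),
        **tot,
    }


def null_window_rate(seed: int, n_reps: int = 200, n_genes: int = 1000,
                     n_imprinted: int = 50, extent: int = 20_000_000,
                     window: int = 1_000_000, step: int = 100_000,
                     alpha: float = 0.05) -> dict:
    """Fraction of sliding windows significant at alpha when imprinted
    genes are placed uniformly at random (no clustering)."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(1, extent, size=n_genes))
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n_genes)],
                          "chrom": "A01", "start": starts,
                          "end": starts + 999, "strand": "+"})
    fractions = []
    for _ in range(n_reps):
        imprinted = rng.choice(genes["gene_id"].to_numpy(),
                               size=n_imprinted, replace=False)
        windows, _ = detect_clusters(imprinted, genes, window=window,
                                     step=step, alpha=alpha)
        fractions.append(float((windows["p"] < alpha).mean()))
    fractions = np.asarray(fractions)
    return {"mean_fraction": float(fractions.mean()),
            "mc_error": float(fractions.std(ddof=1) / np.sqrt(n_reps)),
            "alpha": alpha, "n_reps": n_reps}
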