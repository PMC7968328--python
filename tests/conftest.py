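import numpy as np
import pandas as pd
import pytest

from endoimprint.config import Design, SimConfig
from endoimprint import simulate


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but complete simulated design: 3 chromosomes, 120 genes."""
    return SimConfig(seed=11, n_chrom_a=2, n_chrom_c=1, genes_per_chrom=40,
                     chrom_length=5_000_000, frac_meg=0.10, frac_peg=0.05,
                     corrupt_frac=0.0, stage_switch_frac=0.0)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    genes = simulate.simulate_gene_annotation(small_config)
    truth = simulate.assign_truth(small_config, genes)
    snps = simulate.simulate_parental_variants(small_config, genes)
    depths = simulate.simulate_hybrid_allele_depths(small_config, truth, snps)
    return {"config": small_config, "genes": genes, "truth": truth,
            "snps": snps, "depths": depths,
            "design": Design.from_sim_config(small_config)}


def make_gene_counts(per_gene: dict, stage: str = "20DAP",
                     crosses=("AxB", "BxA")) -> pd.DataFrame:
    """Build a long gene-count table from
    {gene_id: {cross: [(m, p), ...]}} replicate tuples."""
    rows = []
    for gene, by_cross in per_gene.items():
        for cross in crosses:
            for rep, (m, p) in enumerate(by_cross[cross], start=1):
                rows.append((gene, stage, cross, rep, m, p))
    return pd.DataFrame(rows, columns=["gene_id", "stage", "cross",
                                       "replicate", "maternal_reads",
                                       "paternal_reads"])
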