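"""Cluster detection, TE flank enrichment and expression analyses."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from endoimprint import simulate
from endoimprint.config import SimConfig
from endoimprint.context import (classify_tissue_specificity,
                                 compare_expression_imprinted_vs_not,
                                 detect_clusters, fold_change_screen,
                                 gene_flanks, summarize_clusters,
                                 te_flank_enrichment)


def _uniform_genes(n, spacing=100, chrom="A01", length=50):
    starts = 1 + spacing * np.arange(n)
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "chrom": chrom, "start": starts,
                         "end": starts + length - 1, "strand": "+"})


def _hypergeom_tail_enumeration(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact by enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return float(total)


def test_window_p_matches_exhaustive_enumeration_small_universes():
    for N, K in [(10, 3), (20, 6), (30, 10)]:
        genes = _uniform_genes(N, spacing=1000)
        imprinted = [f"g{i}" for i in range(K)]  # first K genes imprinted
        windows, _ = detect_clusters(imprinted, genes, window=5000,
                                     step=5000, alpha=0.05)
        for w in windows.itertuples(index=False):
            expect = _hypergeom_tail_enumeration(w.n_imprinted, N, K,
                                                 w.n_genes_total)
            assert w.p == pytest.approx(expect, abs=1e-12)


def test_dense_imprinted_window_becomes_one_cluster():
    genes = _uniform_genes(1000, spacing=100)
    imprinted = [f"g{i}" for i in range(10)]  # all within the first 1 kb
    windows, clusters = detect_clusters(imprinted, genes, window=5000,
                                        step=5000)
    assert len(clusters) == 1
    assert clusters.loc[0, "n_members"] == 10
    assert clusters.loc[0, "min_p"] < 1e-10


def test_single_imprinted_gene_is_never_a_cluster():
    genes = _uniform_genes(1000, spacing=100)
    windows, clusters = detect_clusters(["g0"], genes, window=1000,
                                        step=1000)
    assert clusters.empty


def test_overlapping_significant_windows_merge():
    genes = _uniform_genes(200, spacing=1000)  # 200 kb of genes
    imprinted = [f"g{i}" for i in range(95, 105)]  # run near 100 kb
    windows, clusters = detect_clusters(imprinted, genes, window=20_000,
                                        step=5_000)
    assert len(clusters) == 1
    assert set(clusters.loc[0, "gene_ids"].split(",")) == set(imprinted)


def test_random_scaffold_genes_are_excluded():
    genes = _uniform_genes(50, spacing=1000)
    rand = _uniform_genes(50, spacing=1000, chrom="Ann_random")
    rand["gene_id"] = [f"r{i}" for i in range(50)]
    both = pd.concat([genes, rand], ignore_index=True)
    imprinted = [f"r{i}" for i in range(10)]  # only on the scaffold
    windows, clusters = detect_clusters(imprinted, both, window=5000,
                                        step=5000)
    assert (windows["chrom"] == "A01").all()
    assert clusters.empty


def test_window_smaller_than_step_raises():
    with pytest.raises(ValueError):
        detect_clusters([], _uniform_genes(10), window=100, step=1000)


def test_empty_universe_raises():
    genes = _uniform_genes(5, chrom="Cnn_random")
    with pytest.raises(ValueError, match="universe"):
        detect_clusters([], genes)


def test_cluster_summary_totals():
    clusters = pd.DataFrame({
        "cluster_id": ["c1", "c2", "c3"],
        "chrom": ["A01", "A02", "C01"],
        "subgenome": ["A", "A", "C"],
        "start": [1, 1, 1], "end": [2, 2, 2],
        "n_members": [3, 4, 2], "min_p": [0.01] * 3,
        "gene_ids": ["", "", ""]})
    s = summarize_clusters(clusters).set_index("subgenome")
    assert s.loc["A", "n_clustered_genes"] == 7
    assert s.loc["total", "n_clusters"] == 3
    assert s.loc["total", "n_clustered_genes"] == 9


# ---------------------------------------------------------------------------
# TE flank enrichment

TOY_GENES = pd.DataFrame({
    "gene_id": ["imp1", "imp2", "non1", "non2"],
    "chrom": "A01",
    "start": [20_000, 60_000, 100_000, 140_000],
    "end": [22_000, 62_000, 102_000, 142_000],
    "strand": "+",
})


def _te(start, end, family="LTR/Copia"):
    return {"chrom": "A01", "start": start, "end": end, "family": family,
            "strand": "+"}


def test_toy_normalized_counts_150_vs_0_per_100_genes():
    # 3 LTR/Copia in the upstream flanks of the 2 imprinted genes, none
    # near the non-imprinted genes -> 150 vs 0 per 100 genes
    tes = pd.DataFrame([_te(16_000, 16_500), _te(17_000, 17_400),
                        _te(56_000, 56_800)])
    rows = te_flank_enrichment(TOY_GENES, ["imp1", "imp2"], tes)
    row = rows[(rows["te_family"] == "LTR/Copia")
               & (rows["region"] == "upstream_5kb")].iloc[0]
    assert row["count_per_100_imprinted"] == 150.0
    assert row["count_per_100_nonimprinted"] == 0.0


def test_te_straddling_the_flank_boundary_is_counted():
    # upstream flank of imp1 is [15000, 19999]; TE 14500-15200 overlaps it
    tes = pd.DataFrame([_te(14_500, 15_200)])
    rows = te_flank_enrichment(TOY_GENES, ["imp1", "imp2"], tes)
    row = rows[(rows["te_family"] == "LTR/Copia")
               & (rows["region"] == "upstream_5kb")].iloc[0]
    assert row["count_imprinted"] == 1


def test_no_tes_emits_rows_with_p_one_and_flag():
    tes = pd.DataFrame(columns=["chrom", "start", "end", "family", "strand"])
    rows = te_flank_enrichment(TOY_GENES, ["imp1"], tes)
    assert (rows["p"] == 1.0).all()
    assert (rows["flag"] == "no_data").all()


def test_flanks_are_strand_aware():
    minus = TOY_GENES.copy()
    minus["strand"] = "-"
    plus_f = gene_flanks(TOY_GENES).set_index(["gene_id", "region"])
    minus_f = gene_flanks(minus).set_index(["gene_id", "region"])
    for gid in TOY_GENES["gene_id"]:
        assert plus_f.loc[(gid, "upstream_5kb"), "start"] == \
            minus_f.loc[(gid, "downstream_5kb"), "start"]


def test_totals_invariant_to_gene_order_and_consistent_strand_flip():
    tes = pd.DataFrame([_te(16_000, 16_500), _te(23_000, 23_500),
                        _te(56_000, 56_800, "LTR/Gypsy")])
    rows_a = te_flank_enrichment(TOY_GENES, ["imp1", "imp2"], tes)
    shuffled = TOY_GENES.sample(frac=1, random_state=1)
    rows_b = te_flank_enrichment(shuffled, ["imp1", "imp2"], tes)
    cols = ["te_family", "region", "count_imprinted", "count_nonimprinted"]
    pd.testing.assert_frame_equal(
        rows_a[cols].sort_values(cols[:2]).reset_index(drop=True),
        rows_b[cols].sort_values(cols[:2]).reset_index(drop=True))
    # flipping every strand swaps the regions but conserves family totals
    flipped = TOY_GENES.copy()
    flipped["strand"] = "-"
    rows_c = te_flank_enrichment(flipped, ["imp1", "imp2"], tes)
    tot = lambda rows: rows.groupby("te_family")[
        ["count_imprinted", "count_nonimprinted"]].sum()
    pd.testing.assert_frame_equal(tot(rows_a), tot(rows_c))


def test_boosted_copia_flanks_are_flagged_significant():
    cfg = SimConfig(seed=21, n_chrom_a=2, n_chrom_c=2, genes_per_chrom=100,
                    chrom_length=5_000_000, frac_meg=0.45, frac_peg=0.05,
                    te_flank_boost=10.0, te_density_per_kb=0.05,
                    cluster_frac=0.0)
    genes = simulate.simulate_gene_annotation(cfg)
    truth = simulate.assign_truth(cfg, genes)
    tes = simulate.simulate_te_annotation(cfg, genes, truth)
    imprinted = truth.loc[truth["true_class"] != "biallelic", "gene_id"]
    rows = te_flank_enrichment(genes, imprinted, tes)
    for region in ("upstream_5kb", "downstream_5kb"):
        row = rows[(rows["te_family"] == "LTR/Copia")
                   & (rows["region"] == region)].iloc[0]
        assert row["p"] < 0.05
        assert row["count_per_100_imprinted"] > \
            row["count_per_100_nonimprinted"]


def test_unboosted_flanks_are_null_calibrated():
    """With te_flank_boost=1 the downstream LTR/Copia test should reject
    at roughly the nominal rate over repeated simulated genomes."""
    n_seeds = 200
    hits = 0
    for seed in range(n_seeds):
        cfg = SimConfig(seed=seed, n_chrom_a=1, n_chrom_c=1,
                        genes_per_chrom=60, chrom_length=2_000_000,
                        frac_meg=0.3, frac_peg=0.0, te_flank_boost=1.0,
                        te_density_per_kb=0.1, cluster_frac=0.0)
        genes = simulate.simulate_gene_annotation(cfg)
        truth = simulate.assign_truth(cfg, genes)
        tes = simulate.simulate_te_annotation(cfg, genes, truth)
        imprinted = truth.loc[truth["true_class"] != "biallelic", "gene_id"]
        rows = te_flank_enrichment(genes, imprinted, tes)
        row = rows[(rows["te_family"] == "LTR/Copia")
                   & (rows["region"] == "downstream_5kb")].iloc[0]
        if row["p"] < 0.05:
            hits += 1
    rate = hits / n_seeds
    mc_err = math.sqrt(0.05 * 0.95 / n_seeds)
    assert rate <= 0.05 + 2 * mc_err


# ---------------------------------------------------------------------------
# expression analyses

def _expr(fpkm_by_gene_tissue: dict) -> pd.DataFrame:
    rows = []
    for gene, tissues in fpkm_by_gene_tissue.items():
        for tissue, v in tissues.items():
            rows.append((gene, tissue, 1, v))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "replicate",
                                       "fpkm"])


ALL_TISSUES = ("endosperm", "root", "stem", "leaf", "bud")


def _profile(endo, other):
    return {t: (endo if t == "endosperm" else other) for t in ALL_TISSUES}


@pytest.mark.parametrize("endo,other,expected", [
    (5.0, 0.2, True),    # endosperm-specific
    (5.0, 3.0, False),   # broadly expressed
    (0.5, 0.5, False),   # not expressed anywhere
])
def test_endosperm_specificity_thresholds(endo, other, expected):
    prof = classify_tissue_specificity(_expr({"g": _profile(endo, other)}))
    assert bool(prof.loc[0, "endosperm_specific"]) is expected


def test_missing_tissue_raises():
    df = _expr({"g": {"endosperm": 5.0, "root": 1.0}})
    with pytest.raises(ValueError, match="tissue"):
        classify_tissue_specificity(df)


def test_identical_groups_give_t_zero():
    vals = {f"i{k}": _profile(v, v) for k, v in
            zip(range(4), [1.0, 2.0, 3.0, 4.0])}
    vals |= {f"n{k}": _profile(v, v) for k, v in
             zip(range(4), [1.0, 2.0, 3.0, 4.0])}
    res = compare_expression_imprinted_vs_not(
        _expr(vals), [f"i{k}" for k in range(4)])
    assert res["t"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_t_statistic_matches_textbook_closed_form():
    rng = np.random.default_rng(6)
    x = rng.normal(5, 1, size=50)
    y = rng.normal(4, 1, size=50)
    vals = {f"i{k}": _profile(2.0 ** x[k] - 1, 1.0) for k in range(50)}
    vals |= {f"n{k}": _profile(2.0 ** y[k] - 1, 1.0) for k in range(50)}
    res = compare_expression_imprinted_vs_not(
        _expr(vals), [f"i{k}" for k in range(50)])
    # Welch t with equal n: (mx - my) / sqrt(s2x/n + s2y/n)
    t_ref = (x.mean() - y.mean()) / math.sqrt(
        x.var(ddof=1) / 50 + y.var(ddof=1) / 50)
    assert res["t"] == pytest.approx(t_ref, abs=1e-9)


def test_log2_shift_of_two_is_detected_at_n_50():
    rng = np.random.default_rng(7)
    base = rng.lognormal(1.0, 0.5, size=50)
    vals = {f"i{k}": _profile(base[k] * 4, 1.0) for k in range(50)}
    vals |= {f"n{k}": _profile(base[k], 1.0) for k in range(50)}
    res = compare_expression_imprinted_vs_not(
        _expr(vals), [f"i{k}" for k in range(50)])
    assert res["p"] < 0.01 and res["stars"] == "**"


def test_group_with_fewer_than_two_genes_raises():
    vals = {"i0": _profile(1.0, 1.0), "n0": _profile(1.0, 1.0),
            "n1": _profile(2.0, 1.0)}
    with pytest.raises(ValueError):
        compare_expression_imprinted_vs_not(_expr(vals), ["i0"])


# ---------------------------------------------------------------------------
# fold-change screen

def test_fold_change_arithmetic_and_flagging():
    hybrid = pd.Series({"g1": 40.0, "g2": 10.0, "g3": 0.0})
    parents = pd.DataFrame({"p1": {"g1": 1.0, "g2": 10.0, "g3": 0.0},
                            "p2": {"g1": 1.0, "g2": 10.0, "g3": 0.0}})
    out = fold_change_screen(hybrid, parents).set_index("gene_id")
    assert out.loc["g1", "log2fc"] == \
        pytest.approx(math.log2(40.01 / 1.01))
    assert bool(out.loc["g1", "flagged"])
    assert out.loc["g2", "log2fc"] == 0.0 and not out.loc["g2", "flagged"]
    assert out.loc["g3", "log2fc"] == 0.0 and not out.loc["g3", "flagged"]


def test_genes_absent_from_one_table_are_skipped():
    hybrid = pd.Series({"g1": 5.0, "g2": 5.0})
    parents = pd.Series({"g1": 5.0})
    out = fold_change_screen(hybrid, parents)
    assert list(out["gene_id"]) == ["g1"]
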