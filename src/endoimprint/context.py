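"""Post-calling genomic context of imprinted genes.

Sliding-window hypergeometric cluster detection along chromosomes,
transposable-element enrichment in strand-aware 5-kb gene flanks,
tissue-specificity classification of FPKM profiles, imprinted vs
non-imprinted expression comparison, and a |log2FC| screen of marker
gene sets.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import is_random_scaffold, parse_subgenome

IMPRINTED_CLASSES = ("MEG", "PEG")
TISSUES = ("endosperm", "root", "stem", "leaf", "bud")


# ---------------------------------------------------------------------------
# sliding-window cluster detection

def detect_clusters(imprinted_ids, gene_models: pd.DataFrame,
                    window: int = 1_000_000, step: int = 100_000,
                    alpha: float = 0.05, min_genes: int = 2
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding 1-Mb / 0.1-Mb-step window scan for imprinted-gene clusters.

    A gene belongs to a window iff its start coordinate lies inside.
    Window enrichment p is the hypergeometric upper tail of observing at
    least the window's imprinted count when drawing its gene total from
    the chromosome-set universe (N genes, K imprinted); genes on
    *_random scaffolds are excluded from both universe and windows.
    Windows with p < alpha and >= min_genes imprinted genes are
    significant; overlapping or adjacent significant windows on one
    chromosome merge into clusters.  Terminal windows are truncated at
    the last gene, not dropped.
    """
    if window < step:
        raise ValueError("window must be >= step")
    placed = gene_models[~gene_models["chrom"].map(is_random_scaffold)]
    if placed.empty:
        raise ValueError("empty gene universe after excluding random "
                         "scaffolds")
    imprinted = set(imprinted_ids)
    N = len(placed)
    K = int(placed["gene_id"].isin(imprinted).sum())

    win_rows = []
    cluster_rows = []
    cluster_counter = 1
    for chrom, sub in placed.groupby("chrom", sort=True):
        starts = np.sort(sub["start"].to_numpy())
        imp_starts = np.sort(
            sub.loc[sub["gene_id"].isin(imprinted), "start"].to_numpy())
        extent = int(sub["end"].max())
        w_starts = np.arange(1, extent + 1, step)
        w_ends = np.minimum(w_starts + window - 1, extent)
        n_genes = (np.searchsorted(starts, w_ends, side="right")
                   - np.searchsorted(starts, w_starts, side="left"))
        n_imp = (np.searchsorted(imp_starts, w_ends, side="right")
                 - np.searchsorted(imp_starts, w_starts, side="left"))
        pvals = stats.hypergeom.sf(n_imp - 1, N, K, n_genes)
        sig = (pvals < alpha) & (n_imp >= min_genes)
        for ws, we, ng, ni, pv, s in zip(w_starts, w_ends, n_genes, n_imp,
                                         pvals, sig):
            win_rows.append((chrom, int(ws), int(we), int(ng), int(ni),
                             float(pv), bool(s)))
        # merge overlapping/adjacent significant windows
        current = None
        merged = []
        for ws, we, pv, s in zip(w_starts, w_ends, pvals, sig):
            if not s:
                continue
            if current is not None and ws <= current[1] + 1:
                current[1] = max(current[1], int(we))
                current[2] = min(current[2], float(pv))
            else:
                if current is not None:
                    merged.append(current)
                current = [int(ws), int(we), float(pv)]
        if current is not None:
            merged.append(current)
        gid_by_start = sub.sort_values("start")
        for ms, me, mp in merged:
            members = gid_by_start[
                (gid_by_start["start"] >= ms) & (gid_by_start["start"] <= me)
                & gid_by_start["gene_id"].isin(imprinted)]["gene_id"].tolist()
            cluster_rows.append((f"cluster_{cluster_counter}", chrom,
                                 parse_subgenome(chrom), ms, me,
                                 len(members), mp, ",".join(members)))
            cluster_counter += 1
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end",
                                              "n_genes_total", "n_imprinted",
                                              "p", "significant"])
    clusters = pd.DataFrame(cluster_rows,
                            columns=["cluster_id", "chrom", "subgenome",
                                     "start", "end", "n_members", "min_p",
                                     "gene_ids"])
    return windows, clusters


def summarize_clusters(clusters: pd.DataFrame) -> pd.DataFrame:
    """Cluster and clustered-gene counts per subgenome plus a total row."""
    rows = []
    total_c, total_g = 0, 0
    if len(clusters):
        for sub, grp in clusters.groupby("subgenome", sort=True):
            rows.append({"subgenome": sub, "n_clusters": len(grp),
                         "n_clustered_genes": int(grp["n_members"].sum())})
            total_c += len(grp)
            total_g += int(grp["n_members"].sum())
    rows.append({"subgenome": "total", "n_clusters": total_c,
                 "n_clustered_genes": total_g})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transposable-element flank enrichment

def gene_flanks(gene_models: pd.DataFrame, flank: int = 5000
                ) -> pd.DataFrame:
    """Strand-aware 5' (upstream) and 3' (downstream) flank intervals,
    truncated at position 1."""
    rows = []
    for g in gene_models.itertuples(index=False):
        if g.strand == "-":
            up = (g.end + 1, g.end + flank)
            down = (max(1, g.start - flank), g.start - 1)
        else:
            up = (max(1, g.start - flank), g.start - 1)
            down = (g.end + 1, g.end + flank)
        for region, (s, e) in (("upstream_5kb", up), ("downstream_5kb",
                                                      down)):
            if e >= s:
                rows.append((g.gene_id, g.chrom, region, s, e))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "region",
                                       "start", "end"])


def te_flank_enrichment(gene_models: pd.DataFrame, imprinted_ids,
                        te_records: pd.DataFrame,
                        flank: int = 5000) -> pd.DataFrame:
    """Per-family TE counts in 5-kb flanks, imprinted vs non-imprinted.

    A TE is counted once for every flank it overlaps (any-overlap rule,
    so elements straddling a flank boundary count).  Counts are
    normalized per 100 genes of each group; the test is a 2x2 chi-square
    of gene-level TE presence/absence vs group, without continuity
    correction.  Degenerate tables give p=1 with a 'no_data' flag.
    """
    imprinted = set(imprinted_ids)
    flanks = gene_flanks(gene_models, flank)
    trees: dict[str, IntervalTree] = {}
    for i, te in enumerate(te_records.itertuples(index=False)):
        trees.setdefault(te.chrom, IntervalTree()).addi(
            te.start, te.end + 1, (i, te.family))
    n_imp = int(gene_models["gene_id"].isin(imprinted).sum())
    n_non = len(gene_models) - n_imp

    families = sorted(set(te_records["family"])) if len(te_records) else []
    regions = ("upstream_5kb", "downstream_5kb")
    # per (family, region, group): total TE hits and genes with >=1 hit
    hit_count: dict = {}
    gene_hit: dict = {}
    for f in flanks.itertuples(index=False):
        group = "imp" if f.gene_id in imprinted else "non"
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        fams_here = {}
        for iv in tree.overlap(f.start, f.end + 1):
            _, fam = iv.data
            fams_here[fam] = fams_here.get(fam, 0) + 1
        for fam, k in fams_here.items():
            hit_count[(fam, f.region, group)] = \
                hit_count.get((fam, f.region, group), 0) + k
            gene_hit[(fam, f.region, group)] = \
                gene_hit.get((fam, f.region, group), 0) + 1

    rows = []
    for fam in families + ["all"]:
        for region in regions:
            if fam == "all":
                ci = sum(v for (f_, r_, g_), v in hit_count.items()
                         if r_ == region and g_ == "imp")
                cn = sum(v for (f_, r_, g_), v in hit_count.items()
                         if r_ == region and g_ == "non")
                gi = min(n_imp, sum(v for (f_, r_, g_), v in gene_hit.items()
                                    if r_ == region and g_ == "imp"))
                gn = min(n_non, sum(v for (f_, r_, g_), v in gene_hit.items()
                                    if r_ == region and g_ == "non"))
            else:
                ci = hit_count.get((fam, region, "imp"), 0)
                cn = hit_count.get((fam, region, "non"), 0)
                gi = gene_hit.get((fam, region, "imp"), 0)
                gn = gene_hit.get((fam, region, "non"), 0)
            table = np.array([[gi, n_imp - gi], [gn, n_non - gn]])
            flag = ""
            if table.sum() == 0 or (table.sum(axis=0) == 0).any() or \
                    (table.sum(axis=1) == 0).any():
                p = 1.0
                flag = "no_data"
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({
                "te_family": fam, "region": region,
                "count_imprinted": ci, "count_nonimprinted": cn,
                "count_per_100_imprinted":
                    100.0 * ci / n_imp if n_imp else 0.0,
                "count_per_100_nonimprinted":
                    100.0 * cn / n_non if n_non else 0.0,
                "genes_with_te_imprinted": gi,
                "genes_with_te_nonimprinted": gn,
                "p": float(p), "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tissue expression

def classify_tissue_specificity(expression: pd.DataFrame,
                                expressed_min: float = 1.0,
                                tissues: tuple[str, ...] = TISSUES
                                ) -> pd.DataFrame:
    """Flag endosperm-specific genes: replicate-mean FPKM >=
    ``expressed_min`` in endosperm and below it in every other tissue.

    ``expression`` is the long (gene_id, tissue, replicate, fpkm) table.
    """
    present = set(expression["tissue"].unique())
    missing = set(tissues) - present
    if missing:
        raise ValueError(f"missing tissue columns: {sorted(missing)}")
    means = (expression.groupby(["gene_id", "tissue"])["fpkm"].mean()
             .unstack("tissue"))
    others = [t for t in tissues if t != "endosperm"]
    specific = (means["endosperm"] >= expressed_min) & \
               (means[others] < expressed_min).all(axis=1)
    out = means[list(tissues)].copy()
    out.columns = [f"fpkm_{t}" for t in tissues]
    out["endosperm_specific"] = specific
    return out.reset_index()


def compare_expression_imprinted_vs_not(expression: pd.DataFrame,
                                        imprinted_ids,
                                        tissue: str = "endosperm",
                                        pseudocount: float = 1.0) -> dict:
    """Welch two-sample t-test on log2(FPKM + pseudocount) between
    imprinted and non-imprinted genes in one tissue."""
    imprinted = set(imprinted_ids)
    sub = expression[expression["tissue"] == tissue]
    means = sub.groupby("gene_id")["fpkm"].mean()
    grp_imp = means[means.index.isin(imprinted)]
    grp_non = means[~means.index.isin(imprinted)]
    if len(grp_imp) < 2 or len(grp_non) < 2:
        raise ValueError("need >= 2 genes in each group")
    x = np.log2(grp_imp.to_numpy() + pseudocount)
    y = np.log2(grp_non.to_numpy() + pseudocount)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {"tissue": tissue, "n_imprinted": len(x), "n_nonimprinted": len(y),
            "mean_log2_imprinted": float(np.mean(x)),
            "mean_log2_nonimprinted": float(np.mean(y)),
            "t": float(t), "p": float(p), "stars": stars}


def fold_change_screen(expression_hybrid: pd.Series,
                       expression_parents: pd.DataFrame | pd.Series,
                       gene_set=None, min_abs_log2fc: float = 5.0,
                       pseudocount: float = 0.01) -> pd.DataFrame:
    """Flag genes whose hybrid/parent expression ratio exceeds the
    |log2FC| threshold.

    ``expression_parents`` may be a Series (already-averaged parental
    mean) or a two-column frame (one column per self-pollinated parent,
    averaged here).  log2FC = log2((hybrid + c) / (parent_mean + c)).
    Genes absent from either table are skipped.
    """
    if isinstance(expression_parents, pd.DataFrame):
        parent_mean = expression_parents.mean(axis=1)
    else:
        parent_mean = expression_parents
    genes = expression_hybrid.index.intersection(parent_mean.index)
    if gene_set is not None:
        genes = genes.intersection(pd.Index(gene_set))
    h = expression_hybrid.loc[genes].astype(float)
    p = parent_mean.loc[genes].astype(float)
    log2fc = np.log2((h + pseudocount) / (p + pseudocount))
    return pd.DataFrame({
        "gene_id": genes,
        "hybrid_mean": h.to_numpy(),
        "parent_mean": p.to_numpy(),
        "log2fc": log2fc.to_numpy(),
        "flagged": (np.abs(log2fc) > min_abs_log2fc).to_numpy(),
    }).reset_index(drop=True)
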