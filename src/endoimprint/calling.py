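"""Imprinted-gene calling against the triploid 2:1 endosperm null.

Per stage, each gene's pooled maternal/paternal counts are tested per
cross with a Pearson chi-square goodness-of-fit against the expected
2m:1p dosage; the two reciprocal crosses are combined conservatively
(a gene must deviate in both, so the combined p is the maximum), FDR is
controlled by Benjamini-Hochberg across depth-passing genes, and the
MEG (maternal:paternal >= 10:1) / PEG (paternal:maternal >= 3:2) ratio
gates plus per-replicate directional consistency are applied in both
cross orientations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ImprintThresholds
from .io import is_random_scaffold, parse_subgenome

IMPRINTED_CLASSES = ("MEG", "PEG")


# ---------------------------------------------------------------------------
# primitive statistics

def chi2_ratio_test(maternal: int, paternal: int,
                    null_ratio: tuple[int, int] = (2, 1)
                    ) -> tuple[float, float]:
    """Pearson goodness-of-fit of (maternal, paternal) counts against an
    expected ratio, df=1, no continuity correction; p is the chi2 upper
    tail.  A zero total is untestable and returns (nan, 1.0)."""
    n = maternal + paternal
    if maternal < 0 or paternal < 0:
        raise ValueError("counts must be >= 0")
    if n == 0:
        return float("nan"), 1.0
    stat, p = _chi2_vec(np.array([maternal]), np.array([paternal]),
                        null_ratio)
    return float(stat[0]), float(p[0])


def _chi2_vec(maternal: np.ndarray, paternal: np.ndarray,
              null_ratio: tuple[int, int] = (2, 1)
              ) -> tuple[np.ndarray, np.ndarray]:
    m = maternal.astype(float)
    p = paternal.astype(float)
    n = m + p
    frac = null_ratio[0] / (null_ratio[0] + null_ratio[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        e_m = n * frac
        e_p = n - e_m
        stat = (m - e_m) ** 2 / e_m + (p - e_p) ** 2 / e_p
    pval = np.where(n > 0, stats.chi2.sf(stat, df=1), 1.0)
    stat = np.where(n > 0, stat, np.nan)
    return stat, pval


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j: p_(j) >= p_(i)} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# per-stage calling

_REQUIRED_COUNT_COLS = ("gene_id", "stage", "cross", "replicate",
                        "maternal_reads", "paternal_reads")


def call_imprinted_genes(gene_counts: pd.DataFrame,
                         thresholds: ImprintThresholds = ImprintThresholds(),
                         stage: str | None = None) -> pd.DataFrame:
    """Classify every gene of one stage as MEG / PEG / biallelic /
    insufficient.

    ``gene_counts`` is the long per-library table (gene_id, stage,
    cross, replicate, maternal_reads, paternal_reads) with both
    reciprocal orientations present and equal replicate structure.  The
    gates, in order:

    1. depth — every library's maternal+paternal >= min_informative_reads,
       otherwise class='insufficient';
    2. chi-square p per cross on within-cross pooled counts, combined
       p = max over crosses, BH q across the stage's depth-passing genes;
    3. MEG iff q <= q_max, pooled maternal >= 10x paternal in both
       crosses, and maternal fraction > 2/3 in every replicate of both
       crosses; PEG analogously (pooled paternal >= 1.5x maternal both
       crosses, paternal fraction > 1/3 in every replicate);
    4. otherwise biallelic.

    Returns one row per gene with counts, fractions, statistics, q,
    class and failure reasons.
    """
    missing = set(_REQUIRED_COUNT_COLS) - set(gene_counts.columns)
    if missing:
        raise ValueError(f"gene_counts missing columns {sorted(missing)}")
    df = gene_counts
    if stage is not None:
        df = df[df["stage"] == stage]
        if df.empty:
            raise ValueError(f"no rows for stage {stage!r}")
    stages = df["stage"].unique()
    if len(stages) != 1:
        raise ValueError("call_imprinted_genes works on one stage at a "
                         "time; pass stage=")
    stage = stages[0]
    crosses = sorted(df["cross"].unique())
    if len(crosses) != 2:
        raise ValueError(f"need both reciprocal orientations, got {crosses}")
    reps_per_cross = {c: sorted(df.loc[df["cross"] == c, "replicate"]
                                .unique()) for c in crosses}
    if reps_per_cross[crosses[0]] != reps_per_cross[crosses[1]]:
        raise ValueError("replicate structure differs between crosses")

    # gene x library matrices (missing libraries count as zero depth)
    wide_m = df.pivot_table(index="gene_id", columns=["cross", "replicate"],
                            values="maternal_reads", aggfunc="sum",
                            fill_value=0)
    wide_p = df.pivot_table(index="gene_id", columns=["cross", "replicate"],
                            values="paternal_reads", aggfunc="sum",
                            fill_value=0)
    full_cols = pd.MultiIndex.from_tuples(
        [(c, r) for c in crosses for r in reps_per_cross[c]])
    wide_m = wide_m.reindex(columns=full_cols, fill_value=0)
    wide_p = wide_p.reindex(columns=full_cols, fill_value=0)
    genes = wide_m.index
    M = wide_m.to_numpy(dtype=np.int64)
    P = wide_p.to_numpy(dtype=np.int64)

    lib_total = M + P
    depth_ok = (lib_total >= thresholds.min_informative_reads).all(axis=1)

    cross_cols = {c: [i for i, (cc, _) in enumerate(full_cols) if cc == c]
                  for c in crosses}
    pooled_m = {c: M[:, cross_cols[c]].sum(axis=1) for c in crosses}
    pooled_p = {c: P[:, cross_cols[c]].sum(axis=1) for c in crosses}

    stat_p = {}
    for c in crosses:
        stat, pv = _chi2_vec(pooled_m[c], pooled_p[c], thresholds.null_ratio)
        stat_p[c] = (stat, pv)
    p_combined = np.maximum(stat_p[crosses[0]][1], stat_p[crosses[1]][1])

    q = np.full(len(genes), np.nan)
    if depth_ok.any():
        q[depth_ok] = bh_fdr(p_combined[depth_ok])

    r = thresholds
    meg_ratio = {c: pooled_m[c] >= r.meg_min_ratio * pooled_p[c]
                 for c in crosses}
    peg_ratio = {c: pooled_p[c] >= r.peg_min_ratio * pooled_m[c]
                 for c in crosses}
    # per-replicate directional consistency (fraction comparisons done
    # multiplicatively on integer counts, so boundaries are exact)
    meg_rep_ok = (M > 2 * P).all(axis=1)        # maternal frac > 2/3
    peg_rep_ok = (2 * P > M).all(axis=1)        # paternal frac > 1/3
    q_ok = np.where(np.isnan(q), False, q <= r.q_max)

    meg = (depth_ok & q_ok & meg_ratio[crosses[0]] & meg_ratio[crosses[1]]
           & meg_rep_ok)
    peg = (depth_ok & q_ok & peg_ratio[crosses[0]] & peg_ratio[crosses[1]]
           & peg_rep_ok)
    cls = np.where(~depth_ok, "insufficient",
                   np.where(meg, "MEG", np.where(peg, "PEG", "biallelic")))

    # failure reasons, evaluated against the direction of the pooled bias
    total_m = pooled_m[crosses[0]] + pooled_m[crosses[1]]
    total_p = pooled_p[crosses[0]] + pooled_p[crosses[1]]
    maternal_leaning = total_m * 1 > 2 * total_p  # above the 2:1 null
    reasons = []
    for i in range(len(genes)):
        if not depth_ok[i]:
            reasons.append("failed_depth")
            continue
        if cls[i] in IMPRINTED_CLASSES:
            reasons.append("")
            continue
        flags = []
        if not q_ok[i]:
            flags.append("failed_q")
        ratio, rep_ok = (meg_ratio, meg_rep_ok) if maternal_leaning[i] \
            else (peg_ratio, peg_rep_ok)
        if not ratio[crosses[0]][i]:
            flags.append("failed_ratio_cross1")
        if not ratio[crosses[1]][i]:
            flags.append("failed_ratio_cross2")
        if not rep_ok[i]:
            flags.append("failed_replicate_consistency")
        reasons.append(",".join(flags))

    def _frac(m, p):
        tot = m + p
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, m / np.maximum(tot, 1), np.nan)

    out = pd.DataFrame({
        "gene_id": genes,
        "stage": stage,
        "maternal_cross1": pooled_m[crosses[0]],
        "paternal_cross1": pooled_p[crosses[0]],
        "maternal_frac_cross1": _frac(pooled_m[crosses[0]],
                                      pooled_p[crosses[0]]),
        "chi2_cross1": stat_p[crosses[0]][0],
        "p_cross1": stat_p[crosses[0]][1],
        "maternal_cross2": pooled_m[crosses[1]],
        "paternal_cross2": pooled_p[crosses[1]],
        "maternal_frac_cross2": _frac(pooled_m[crosses[1]],
                                      pooled_p[crosses[1]]),
        "chi2_cross2": stat_p[crosses[1]][0],
        "p_cross2": stat_p[crosses[1]][1],
        "p_combined": p_combined,
        "q": q,
        "class": cls,
        "reasons": reasons,
    })
    out.attrs["crosses"] = crosses
    out.attrs["thresholds"] = r
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage comparison and bookkeeping

def stage_overlap_from_counts(n_stage1: int, n_stage2: int,
                              n_both: int) -> dict[str, int]:
    """Inclusion-exclusion bookkeeping for a two-stage Venn diagram."""
    if n_both > min(n_stage1, n_stage2):
        raise ValueError("intersection cannot exceed either stage count")
    return {
        "n_stage1": n_stage1,
        "n_stage2": n_stage2,
        "n_both": n_both,
        "union": n_stage1 + n_stage2 - n_both,
        "only_stage1": n_stage1 - n_both,
        "only_stage2": n_stage2 - n_both,
    }


def summarize_stage_overlap(calls_stage1: pd.DataFrame,
                            calls_stage2: pd.DataFrame) -> pd.DataFrame:
    """Per-class and total imprinted-gene counts at each stage, their
    intersection (same class in both stages for the per-class rows;
    imprinted in both for the total row) and the union."""
    rows = []
    sets1 = {c: set(calls_stage1.loc[calls_stage1["class"] == c, "gene_id"])
             for c in IMPRINTED_CLASSES}
    sets2 = {c: set(calls_stage2.loc[calls_stage2["class"] == c, "gene_id"])
             for c in IMPRINTED_CLASSES}
    for c in IMPRINTED_CLASSES:
        d = stage_overlap_from_counts(len(sets1[c]), len(sets2[c]),
                                      len(sets1[c] & sets2[c]))
        rows.append({"class": c, **d})
    all1 = sets1["MEG"] | sets1["PEG"]
    all2 = sets2["MEG"] | sets2["PEG"]
    d = stage_overlap_from_counts(len(all1), len(all2), len(all1 & all2))
    rows.append({"class": "imprinted", **d})
    return pd.DataFrame(rows)


def compare_stages(calls_stage1: pd.DataFrame,
                   calls_stage2: pd.DataFrame) -> pd.DataFrame:
    """Per-gene cross-stage category.

    continuous: imprinted with the same class in both stages;
    one_stage_biallelic_other / one_stage_insufficient_other: imprinted
    in exactly one stage with the stated class in the other;
    class_switch: MEG in one stage, PEG in the other (reported
    separately); not_imprinted otherwise.
    """
    c1 = calls_stage1.set_index("gene_id")["class"]
    c2 = calls_stage2.set_index("gene_id")["class"]
    universe = c1.index.union(c2.index)
    a = c1.reindex(universe).fillna("insufficient")
    b = c2.reindex(universe).fillna("insufficient")
    cats = []
    for g in universe:
        x, y = a[g], b[g]
        xi, yi = x in IMPRINTED_CLASSES, y in IMPRINTED_CLASSES
        if xi and yi:
            cats.append("continuous" if x == y else "class_switch")
        elif xi or yi:
            other = y if xi else x
            cats.append("one_stage_biallelic_other"
                        if other == "biallelic"
                        else "one_stage_insufficient_other")
        else:
            cats.append("not_imprinted")
    return pd.DataFrame({"gene_id": universe, "class_stage1": a.values,
                         "class_stage2": b.values, "category": cats})


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``ndigits``."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round(100.0 * part / whole, ndigits)


def subgenome_bias_summary(imprinted_calls: pd.DataFrame,
                           gene_models: pd.DataFrame,
                           homolog_pairs: pd.DataFrame | None = None
                           ) -> dict:
    """Split imprinted genes into homolog-paired (both members imprinted)
    and unpaired, and report the unpaired A/C subgenome counts with
    nearest-integer percentages.

    ``homolog_pairs`` needs columns gene_a / gene_c; genes on *_random
    scaffolds keep their subgenome letter but are flagged in the
    'random_scaffold' count; unparseable chromosome names fall into the
    'unplaced' bucket.
    """
    imprinted = imprinted_calls.loc[
        imprinted_calls["class"].isin(IMPRINTED_CLASSES), "gene_id"]
    imprinted = set(imprinted)
    chrom_of = gene_models.set_index("gene_id")["chrom"]

    pairs = []
    paired_genes: set[str] = set()
    if homolog_pairs is not None and len(homolog_pairs):
        for row in homolog_pairs.itertuples(index=False):
            ga, gc = row.gene_a, row.gene_c
            if ga in imprinted and gc in imprinted:
                pairs.append((ga, gc))
                paired_genes.update((ga, gc))
    unpaired = imprinted - paired_genes

    counts = {"A": 0, "C": 0, "unplaced": 0}
    n_random = 0
    for g in sorted(unpaired):
        chrom = chrom_of.get(g)
        sub = parse_subgenome(chrom) if chrom is not None else "unplaced"
        counts[sub] = counts.get(sub, 0) + 1
        if chrom is not None and is_random_scaffold(chrom):
            n_random += 1
    placed = counts["A"] + counts["C"]
    pct_a = int(round(100.0 * counts["A"] / placed)) if placed else 0
    pct_c = int(round(100.0 * counts["C"] / placed)) if placed else 0
    return {
        "n_imprinted": len(imprinted),
        "n_pairs_both_imprinted": len(pairs),
        "pairs": pairs,
        "n_unpaired": len(unpaired),
        "unpaired_A": counts["A"],
        "unpaired_C": counts["C"],
        "unpaired_unplaced": counts["unplaced"],
        "random_scaffold": n_random,
        "pct_A": pct_a,
        "pct_C": pct_c,
    }
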