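"""Seeded synthetic reciprocal-cross endosperm dataset with exported truth.

The generator emulates the study design this pipeline targets: two
homozygous oilseed-rape cultivars differing at exonic SNPs, reciprocal
crosses with three biological replicates, endosperm sampled at two
stages, triploid 2:1 maternal:paternal allelic dosage for biallelic
genes, injected MEGs/PEGs (a subset clustered on chromosomes), elevated
TE density in imprinted-gene flanks, and tissue FPKM profiles with an
endosperm-specific subset.  Every artifact is a pure function of the
:class:`~endoimprint.config.SimConfig` (identical seed, identical bytes).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import Design, SimConfig, config_hash
from . import io

# independent RNG streams per component so adding draws to one stage
# does not perturb the others
_STREAM_ANNOT = 1
_STREAM_TRUTH = 2
_STREAM_VARIANTS = 3
_STREAM_HYBRID = 4
_STREAM_TE = 5
_STREAM_EXPR = 6

TE_FAMILIES = ("LTR/Copia", "LTR/Gypsy", "DNA/MuDR", "CACTA", "other")
_TE_BG_PROBS = np.array([0.25, 0.25, 0.20, 0.15, 0.15])
# boosted insertions near imprinted genes skew to LTR/Copia
_TE_BOOST_PROBS = np.array([0.60, 0.15, 0.10, 0.05, 0.10])

_BASES = np.array(list("ACGT"))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


# ---------------------------------------------------------------------------
# gene annotation

def simulate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Place non-overlapping genes on the A/C chromosomes.

    Returns a frame (gene_id, chrom, start, end, strand, subgenome) with
    1-based inclusive coordinates; chromosome names 'A01'.. / 'C01'..
    make the subgenome derivable from the name.
    """
    rng = _rng(config, _STREAM_ANNOT)
    lo, hi = config.gene_length_range
    # pigeonhole: every gene needs its span plus a 1 bp gap
    if config.genes_per_chrom * (hi + 1) > config.chrom_length:
        raise ValueError(
            f"chromosome of {config.chrom_length} bp too short for "
            f"{config.genes_per_chrom} genes of up to {hi} bp")
    rows = []
    for chrom in config.chrom_names:
        n = config.genes_per_chrom
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = config.chrom_length - int(lengths.sum()) - n
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        strands = rng.choice(np.array(["+", "-"]), size=n)
        pos = 0
        for i in range(n):
            start = pos + gaps[i] + 1
            end = start + int(lengths[i]) - 1
            rows.append((f"{chrom}g{i + 1:04d}", chrom, start, end,
                         strands[i]))
            pos = end + 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
    genes["subgenome"] = genes["chrom"].map(io.parse_subgenome)
    return genes


# ---------------------------------------------------------------------------
# ground truth: imprinting classes, clusters, stage consistency

def assign_truth(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene a true imprinting class and cluster membership.

    ``cluster_frac`` of the imprinted genes are laid down as runs of
    consecutive genes on a chromosome (an imprinting cluster); the rest
    are scattered uniformly.  ``stage_switch_frac`` of imprinted genes
    are imprinted in only one randomly chosen stage, mirroring the
    predominance of stage-specific imprinting in real endosperm.
    """
    rng = _rng(config, _STREAM_TRUTH)
    n = len(genes)
    n_meg = int(round(n * config.frac_meg))
    n_peg = int(round(n * config.frac_peg))
    n_imp = n_meg + n_peg

    order = genes.reset_index(drop=True)
    cluster_of = np.full(n, -1)
    imprinted = np.zeros(n, dtype=bool)

    n_clustered_target = int(round(n_imp * config.cluster_frac))
    lo, hi = config.cluster_size_range
    chrom_index = {c: np.flatnonzero((order["chrom"] == c).to_numpy())
                   for c in order["chrom"].unique()}
    cluster_id = 0
    placed = 0
    attempts = 0
    while placed < n_clustered_target and attempts < 10_000:
        attempts += 1
        chrom = rng.choice(list(chrom_index))
        idx = chrom_index[chrom]
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n_clustered_target - placed + 1, len(idx))
        if size < 2:
            size = 2
        start = int(rng.integers(0, len(idx) - size + 1))
        members = idx[start:start + size]
        if imprinted[members].any():
            continue
        imprinted[members] = True
        cluster_of[members] = cluster_id
        cluster_id += 1
        placed += size
    remaining = n_imp - placed
    if remaining > 0:
        free = np.flatnonzero(~imprinted)
        chosen = rng.choice(free, size=remaining, replace=False)
        imprinted[chosen] = True

    imp_idx = np.flatnonzero(imprinted)
    rng.shuffle(imp_idx)
    peg_idx = set(imp_idx[:n_peg].tolist())

    classes = np.array(["biallelic"] * n, dtype=object)
    mfrac = np.full(n, 2.0 / 3.0)
    for i in imp_idx:
        if i in peg_idx:
            classes[i] = "PEG"
            mfrac[i] = 1.0 - config.peg_paternal_frac
        else:
            classes[i] = "MEG"
            mfrac[i] = config.meg_maternal_frac

    truth = order[["gene_id", "chrom", "subgenome"]].copy()
    truth["true_class"] = classes
    truth["maternal_frac_true"] = mfrac
    truth["cluster_id"] = [f"truth_cluster_{c}" if c >= 0 else ""
                           for c in cluster_of]

    # per-stage classes: switchers are imprinted in one stage only
    n_switch = int(round(len(imp_idx) * config.stage_switch_frac))
    switchers = set(rng.choice(imp_idx, size=n_switch, replace=False).tolist()) \
        if n_switch else set()
    stage_on = {i: rng.choice(len(config.stages)) for i in switchers}
    for s_i, stage in enumerate(config.stages):
        col = []
        for i in range(n):
            if classes[i] == "biallelic":
                col.append("biallelic")
            elif i in switchers and stage_on[i] != s_i:
                col.append("biallelic")
            else:
                col.append(classes[i])
        truth[f"class_{stage}"] = col
    return truth


# ---------------------------------------------------------------------------
# parental diagnostic SNPs and per-replicate variant calls

def simulate_parental_variants(config: SimConfig,
                               genes: pd.DataFrame) -> pd.DataFrame:
    """Draw diagnostic SNP sites inside genes, with per-site corruption.

    Each site has both lines homozygous for different alleles.  A
    ``corrupt_frac`` fraction of sites is damaged to exercise the
    downstream filters: either one library is dropped to depth 9
    ('low_depth') or one replicate of one line is made heterozygous
    ('het').  Returns a frame with columns chrom, pos, gene_id, ref,
    alt, allele_line1, allele_line2, corruption, corrupt_line,
    corrupt_rep.
    """
    rng = _rng(config, _STREAM_VARIANTS)
    rows = []
    extra = max(config.snps_per_gene - 1.0, 0.0)
    for g in genes.itertuples(index=False):
        k = 1 + int(rng.poisson(extra))
        span = g.end - g.start + 1
        k = min(k, span)
        offsets = np.sort(rng.choice(span, size=k, replace=False))
        for off in offsets:
            ref, alt = rng.choice(4, size=2, replace=False)
            line1_has_alt = bool(rng.random() < 0.5)
            rows.append((
                g.chrom, int(g.start + off), g.gene_id,
                _BASES[ref], _BASES[alt],
                _BASES[alt] if line1_has_alt else _BASES[ref],
                _BASES[ref] if line1_has_alt else _BASES[alt],
            ))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "ref",
                                       "alt", "allele_line1",
                                       "allele_line2"])
    snps["corruption"] = "none"
    snps["corrupt_line"] = ""
    snps["corrupt_rep"] = 0
    n_corrupt = int(round(len(snps) * config.corrupt_frac))
    if n_corrupt:
        idx = rng.choice(len(snps), size=n_corrupt, replace=False)
        kinds = np.where(np.arange(n_corrupt) % 2 == 0, "low_depth", "het")
        lines = rng.choice([config.line1, config.line2], size=n_corrupt)
        reps = rng.integers(1, config.n_replicates + 1, size=n_corrupt)
        snps.loc[idx, "corruption"] = kinds
        snps.loc[idx, "corrupt_line"] = lines
        snps.loc[idx, "corrupt_rep"] = reps
    return snps


def parental_vcf_records(config: SimConfig, snps: pd.DataFrame,
                         line: str, replicate: int) -> pd.DataFrame:
    """Per-replicate single-sample VCF rows for one parental line."""
    line_idx = 0 if line == config.line1 else 1
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, _STREAM_VARIANTS, 100,
                                line_idx, replicate)))
    n = len(snps)
    # depth floor at the screen's cutoff so uncorrupted sites always pass
    dp = np.maximum(rng.poisson(config.depth_mean, size=n), 10)
    allele_col = "allele_line1" if line == config.line1 else "allele_line2"
    rows = []
    for i, s in enumerate(snps.itertuples(index=False)):
        depth = int(dp[i])
        gt = "1/1" if getattr(s, allele_col) == s.alt else "0/0"
        ad_ref, ad_alt = (0, depth) if gt == "1/1" else (depth, 0)
        if s.corrupt_line == line and s.corrupt_rep == replicate:
            if s.corruption == "low_depth":
                depth = 9
                ad_ref, ad_alt = (0, 9) if gt == "1/1" else (9, 0)
            elif s.corruption == "het":
                gt = "0/1"
                ad_ref, ad_alt = depth - depth // 2, depth // 2
        rows.append((s.chrom, s.pos, s.ref, s.alt, gt, ad_ref, ad_alt,
                     depth))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt",
                                       "ad_ref", "ad_alt", "dp"])


# ---------------------------------------------------------------------------
# hybrid endosperm allele depths

def _beta_binomial_p(rng: np.random.Generator, mu: np.ndarray,
                     rho: float) -> np.ndarray:
    """Per-observation success probability: Beta-distributed around mu
    with intra-class correlation rho (rho=0 degenerates to mu)."""
    if rho == 0.0:
        return mu
    scale = (1.0 - rho) / rho
    a = np.clip(mu * scale, 1e-9, None)
    b = np.clip((1.0 - mu) * scale, 1e-9, None)
    # degenerate effect sizes (mu of exactly 0 or 1) stay degenerate
    out = rng.beta(a, b)
    out[mu == 0.0] = 0.0
    out[mu == 1.0] = 1.0
    return out


def simulate_hybrid_allele_depths(config: SimConfig, truth: pd.DataFrame,
                                  snps: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP parental allele depths for every stage x cross x replicate.

    Biallelic genes draw maternal reads around the triploid null (2/3);
    MEGs around ``meg_maternal_frac``; PEGs around
    ``1 - peg_paternal_frac``.  The maternal allele follows the mother
    line of each cross orientation, so the same gene is maternally
    biased toward opposite line alleles in the two reciprocal crosses.

    Returns a long frame: chrom, pos, gene_id, stage, cross, replicate,
    count_line1, count_line2.
    """
    rng = _rng(config, _STREAM_HYBRID)
    truth = truth.set_index("gene_id")
    missing = truth.index.difference(snps["gene_id"].unique())
    if len(missing):
        warnings.warn(f"{len(missing)} genes have no diagnostic SNP and "
                      "will have zero informative depth")
    snp_gene = snps["gene_id"].to_numpy()
    n_snp = len(snps)
    snps_per_gene = snps.groupby("gene_id").size()
    per_snp_mean = (config.depth_mean /
                    snps_per_gene.reindex(snp_gene).to_numpy())

    frames = []
    for stage in config.stages:
        class_col = truth[f"class_{stage}"]
        mu_gene = pd.Series(2.0 / 3.0, index=truth.index)
        mu_gene[class_col == "MEG"] = config.meg_maternal_frac
        mu_gene[class_col == "PEG"] = 1.0 - config.peg_paternal_frac
        for cross in config.crosses:
            mother_is_line1 = cross.mother == config.line1
            for rep in range(1, config.n_replicates + 1):
                # one effective maternal fraction per gene per library
                p_gene = _beta_binomial_p(
                    rng, mu_gene.to_numpy().copy(), config.overdispersion)
                p_snp = pd.Series(p_gene, index=truth.index)\
                    .reindex(snp_gene).to_numpy()
                depth = rng.poisson(per_snp_mean, size=n_snp)
                maternal = rng.binomial(depth, p_snp)
                paternal = depth - maternal
                c1 = maternal if mother_is_line1 else paternal
                c2 = paternal if mother_is_line1 else maternal
                frames.append(pd.DataFrame({
                    "chrom": snps["chrom"].to_numpy(),
                    "pos": snps["pos"].to_numpy(),
                    "gene_id": snp_gene,
                    "stage": stage,
                    "cross": cross.cross_id,
                    "replicate": rep,
                    "count_line1": c1,
                    "count_line2": c2,
                }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# transposable elements

def simulate_te_annotation(config: SimConfig, genes: pd.DataFrame,
                           truth: pd.DataFrame,
                           flank: int = 5000) -> pd.DataFrame:
    """TE intervals with family labels; imprinted-gene flanks enriched.

    Background insertions are uniform along each chromosome at
    ``te_density_per_kb``; the 5-kb flanks of truly imprinted genes
    additionally receive Poisson extras so their total placement rate is
    ``baseline * te_flank_boost``, with the extra insertions biased to
    LTR/Copia.
    """
    rng = _rng(config, _STREAM_TE)
    rows = []
    fam_arr = np.array(TE_FAMILIES, dtype=object)
    for chrom in config.chrom_names:
        lam = config.chrom_length / 1000.0 * config.te_density_per_kb
        n_bg = rng.poisson(lam)
        if n_bg:
            starts = np.sort(rng.integers(1, config.chrom_length, size=n_bg))
            lengths = rng.integers(200, 3000, size=n_bg)
            fams = rng.choice(fam_arr, size=n_bg, p=_TE_BG_PROBS)
            strands = rng.choice(np.array(["+", "-"]), size=n_bg)
            for s, ln, fm, st in zip(starts, lengths, fams, strands):
                rows.append((chrom, int(s),
                             int(min(s + ln - 1, config.chrom_length)),
                             fm, st))
    imp = truth[truth["true_class"] != "biallelic"]["gene_id"]
    gidx = genes.set_index("gene_id")
    base_flank_rate = flank / 1000.0 * config.te_density_per_kb
    extra_rate = base_flank_rate * max(config.te_flank_boost - 1.0, 0.0)
    for gid in imp:
        g = gidx.loc[gid]
        for flank_start, flank_end in (
                (max(1, g.start - flank), g.start - 1),
                (g.end + 1, min(config.chrom_length, g.end + flank))):
            if flank_end < flank_start:
                continue
            n_extra = rng.poisson(extra_rate)
            for _ in range(int(n_extra)):
                s = int(rng.integers(flank_start, flank_end + 1))
                ln = int(rng.integers(200, 3000))
                fm = rng.choice(fam_arr, p=_TE_BOOST_PROBS)
                st = rng.choice(np.array(["+", "-"]))
                rows.append((g.chrom, s, min(s + ln - 1, config.chrom_length),
                             fm, st))
    tes = pd.DataFrame(rows, columns=["chrom", "start", "end", "family",
                                      "strand"])
    return tes.sort_values(["chrom", "start", "end", "family"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tissue expression matrix

TISSUES = ("endosperm", "root", "stem", "leaf", "bud")


def simulate_expression_matrix(config: SimConfig, truth: pd.DataFrame,
                               n_replicates: int = 3
                               ) -> tuple[pd.DataFrame, list[str]]:
    """Log-normal FPKM over five tissues; a configurable fraction of the
    imprinted genes is made endosperm-specific (>= 1 FPKM in endosperm,
    < 1 elsewhere); every other gene is forced to be expressed in at
    least one non-endosperm tissue so the designated set is recoverable
    exactly.  Returns (long frame, endosperm-specific gene ids)."""
    rng = _rng(config, _STREAM_EXPR)
    gene_ids = truth["gene_id"].to_numpy()
    n = len(gene_ids)
    imp_ids = truth.loc[truth["true_class"] != "biallelic", "gene_id"]
    n_spec = int(round(len(imp_ids) * config.endosperm_specific_frac))
    specific = sorted(rng.choice(imp_ids.to_numpy(), size=n_spec,
                                 replace=False).tolist()) if n_spec else []
    spec_set = set(specific)

    base = rng.lognormal(mean=1.0, sigma=1.0, size=(n, len(TISSUES)))
    # guarantee non-specific genes are expressed somewhere outside endosperm
    anchor_tissue = rng.integers(1, len(TISSUES), size=n)
    rows = []
    for j, tissue in enumerate(TISSUES):
        means = base[:, j].copy()
        for i, gid in enumerate(gene_ids):
            if gid in spec_set:
                if tissue == "endosperm":
                    means[i] = max(means[i], 2.0)
                else:
                    means[i] = min(means[i], 0.5)
            elif j == anchor_tissue[i]:
                means[i] = max(means[i], 1.5)
        noise = rng.lognormal(mean=0.0, sigma=0.05,
                              size=(n, n_replicates))
        for rep in range(1, n_replicates + 1):
            rows.append(pd.DataFrame({
                "gene_id": gene_ids,
                "tissue": tissue,
                "replicate": rep,
                "fpkm": np.round(means * noise[:, rep - 1], 4),
            }))
    expr = pd.concat(rows, ignore_index=True)
    return expr, specific


# ---------------------------------------------------------------------------
# full bundle

def write_bundle(config: SimConfig, out_dir) -> dict[str, str]:
    """Generate and write the complete fixture bundle; returns a manifest
    mapping artifact names to paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(config), "seed": config.seed}

    genes = simulate_gene_annotation(config)
    truth = assign_truth(config, genes)
    snps = simulate_parental_variants(config, genes)
    depths = simulate_hybrid_allele_depths(config, truth, snps)
    tes = simulate_te_annotation(config, genes, truth)
    expr, specific = simulate_expression_matrix(
        config, truth, n_replicates=config.n_replicates)
    design = Design.from_sim_config(config)

    manifest: dict[str, str] = {}

    def _reg(name, path):
        manifest[name] = str(path)
        return path

    io.write_gene_models_gff3(genes, _reg("genes_gff3", out / "genes.gff3"))
    io.write_tsv(truth, _reg("truth_tsv", out / "truth.tsv"), meta)
    io.write_tsv(snps, _reg("snp_truth_tsv", out / "snp_truth.tsv"), meta)
    contigs = {c: config.chrom_length for c in config.chrom_names}
    for line in (config.line1, config.line2):
        for rep in range(1, config.n_replicates + 1):
            recs = parental_vcf_records(config, snps, line, rep)
            path = out / f"parent_{line}_rep{rep}.vcf"
            io.write_parent_vcf(recs, path, f"{line}_rep{rep}", contigs)
            _reg(f"vcf_{line}_rep{rep}", path)
    io.write_tsv(depths, _reg("allele_depths_tsv", out / "allele_depths.tsv"),
                 meta)
    io.write_te_bed(tes, _reg("te_bed", out / "tes.bed"))
    io.write_tsv(expr, _reg("expression_tsv", out / "expression.tsv"), meta)
    io.write_tsv(pd.DataFrame({"gene_id": specific}),
                 _reg("endosperm_specific_truth_tsv",
                      out / "endosperm_specific_truth.tsv"), meta)
    design.to_yaml(_reg("design_yaml", out / "design.yaml"))
    with open(_reg("sim_config_yaml", out / "sim_config.yaml"), "w") as fh:
        from dataclasses import asdict
        d = asdict(config)
        d["stages"] = list(d["stages"])
        d["gene_length_range"] = list(d["gene_length_range"])
        d["cluster_size_range"] = list(d["cluster_size_range"])
        yaml.safe_dump(d, fh, sort_keys=False)
    return manifest
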