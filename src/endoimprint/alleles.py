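"""Tally parental allele support at diagnostic SNPs in hybrid libraries.

Two entry points produce the same per-SNP :class:`AlleleDepth` records:
a SAM/BAM walk over aligned endosperm reads, and a pre-tabulated
allele-depth table (the simulator's output format).  Counts are then
oriented maternal/paternal by the cross design and aggregated to gene
level.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .config import Design
from .snps import ParentalSnp

logger = logging.getLogger(__name__)

DEPTH_TABLE_COLUMNS = ["chrom", "pos", "gene_id", "stage", "cross",
                       "replicate", "count_line1", "count_line2"]


@dataclass
class AlleleDepth:
    """Per-SNP, per-library parental-line read counts."""

    chrom: str
    pos: int
    library_id: str
    count_line1: int
    count_line2: int
    count_other: int = 0

    def __post_init__(self) -> None:
        if min(self.count_line1, self.count_line2, self.count_other) < 0:
            raise ValueError("allele counts must be >= 0")


def count_alleles_from_alignments(sam_path, snps: list[ParentalSnp],
                                  library_id: str, min_mapq: int = 20,
                                  min_baseq: int = 20) -> list[AlleleDepth]:
    """Walk coordinate-sorted alignments and tally line-of-origin bases.

    'Uniquely mapped' is operationalized as: primary, non-supplementary,
    non-duplicate, MAPQ >= ``min_mapq`` and, when an NH tag is present,
    NH == 1.  A read covering k SNPs contributes at up to k sites
    (per-locus tallying); bases below ``min_baseq`` and positions
    deleted in the read contribute nothing.
    """
    by_chrom_pos: dict[str, list[int]] = {}
    alleles: dict[tuple[str, int], tuple[str, str]] = {}
    for s in snps:
        key = (s.chrom, s.pos)
        if key not in alleles:
            by_chrom_pos.setdefault(s.chrom, []).append(s.pos)
        alleles[key] = (s.allele_line1, s.allele_line2)
    for positions in by_chrom_pos.values():
        positions.sort()

    counts: dict[tuple[str, int], list[int]] = {
        key: [0, 0, 0] for key in alleles}
    last_seen: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        header_chroms = set(sam.references or ())
        for chrom in by_chrom_pos:
            if header_chroms and chrom not in header_chroms:
                logger.warning("SNP chromosome %s absent from alignment "
                               "header", chrom)
        for read in sam:
            if read.is_unmapped or read.is_secondary or \
                    read.is_supplementary or read.is_duplicate:
                continue
            chrom = read.reference_name
            if read.reference_start < last_seen.get(chrom, -1):
                raise ValueError(f"input not coordinate-sorted at "
                                 f"{chrom}:{read.reference_start + 1}")
            last_seen[chrom] = read.reference_start
            if read.mapping_quality < min_mapq:
                continue
            if read.has_tag("NH") and read.get_tag("NH") != 1:
                continue
            positions = by_chrom_pos.get(chrom)
            if not positions:
                continue
            lo = bisect_left(positions, read.reference_start + 1)
            hi = bisect_right(positions, read.reference_end or 0)
            if lo >= hi:
                continue
            wanted = set(positions[lo:hi])
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                if pos1 not in wanted:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos]
                a1, a2 = alleles[(chrom, pos1)]
                slot = 0 if base == a1 else 1 if base == a2 else 2
                counts[(chrom, pos1)][slot] += 1
    return [AlleleDepth(chrom, pos, library_id, c[0], c[1], c[2])
            for (chrom, pos), c in sorted(counts.items())]


def load_allele_depths_from_table(path) -> pd.DataFrame:
    """Parse the simulator's long allele-depth TSV losslessly.

    Schema: chrom, pos, gene_id, stage, cross, replicate, count_line1,
    count_line2.  Malformed or negative rows raise with the offending
    line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "stage": str, "cross": str})
    missing = set(DEPTH_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-depth table missing columns: "
                         f"{sorted(missing)}")
    for col in ("count_line1", "count_line2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"malformed or negative {col} near line {row}")
        df[col] = vals.astype(int)
    return df


def orient_counts_by_cross(depths: pd.DataFrame, design: Design
                           ) -> pd.DataFrame:
    """Map line counts to (maternal, paternal) by each row's cross.

    line1 = design.lines[0].  Rows whose cross is absent from the
    design raise; 'count_other' columns, when present, are discarded
    with a logged total.
    """
    known = {c.cross_id: c for c in design.crosses}
    unknown = set(depths["cross"].unique()) - set(known)
    if unknown:
        raise KeyError(f"crosses not in design: {sorted(unknown)}")
    line1 = design.lines[0]
    mother_is_line1 = depths["cross"].map(
        lambda cid: known[cid].mother == line1)
    out = depths.copy()
    c1 = out["count_line1"].to_numpy()
    c2 = out["count_line2"].to_numpy()
    flip = ~mother_is_line1.to_numpy()
    maternal = np.where(flip, c2, c1)
    paternal = np.where(flip, c1, c2)
    out["maternal"] = maternal
    out["paternal"] = paternal
    if "count_other" in out.columns:
        discarded = int(out["count_other"].sum())
        if discarded:
            logger.info("discarded %d reads matching neither parental "
                        "allele", discarded)
        out = out.drop(columns=["count_other"])
    return out.drop(columns=["count_line1", "count_line2"])


def aggregate_gene_counts(oriented: pd.DataFrame,
                          snp_gene_map: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Sum oriented SNP counts to gene level per (stage, cross, replicate).

    If ``oriented`` lacks a gene_id column, ``snp_gene_map`` (chrom,
    pos, gene_id; one row per SNP-gene assignment) supplies it; a SNP
    inside two overlapping genes contributes to both gene totals (the
    documented double-count contract).  Genes with no informative SNP
    are absent from the result.
    """
    df = oriented
    if "gene_id" not in df.columns or df["gene_id"].isna().all():
        if snp_gene_map is None:
            raise ValueError("need gene_id column or a snp_gene_map")
        df = df.drop(columns=["gene_id"], errors="ignore").merge(
            snp_gene_map[["chrom", "pos", "gene_id"]],
            on=["chrom", "pos"], how="inner")
    df = df.dropna(subset=["gene_id"])
    grouped = (df.groupby(["gene_id", "stage", "cross", "replicate"],
                          as_index=False)[["maternal", "paternal"]]
               .sum())
    return grouped.rename(columns={"maternal": "maternal_reads",
                                   "paternal": "paternal_reads"})


def depths_records_to_frame(records: list[AlleleDepth],
                            design: Design) -> pd.DataFrame:
    """Convert SAM-path AlleleDepth records into the long table schema,
    resolving each library_id (stage_cross_repN) via the design."""
    libs = design.libraries()
    rows = []
    for r in records:
        if r.library_id not in libs:
            raise KeyError(f"library {r.library_id!r} not in design")
        lib = libs[r.library_id]
        rows.append((r.chrom, r.pos, lib["stage"], lib["cross"],
                     lib["replicate"], r.count_line1, r.count_line2,
                     r.count_other))
    return pd.DataFrame(rows, columns=["chrom", "pos", "stage", "cross",
                                       "replicate", "count_line1",
                                       "count_line2", "count_other"])
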