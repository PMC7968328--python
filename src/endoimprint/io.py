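"""Readers and writers for the interchange formats used by the pipeline.

Coordinate conventions: GFF3, VCF and all internal tables are 1-based
inclusive; BED is converted to/from 0-based half-open only at the file
boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd

from . import __version__

_SUBGENOME_RE = re.compile(r"^(?:Bna)?([AC])(?:nn_random|nng?\b|\d+)", re.IGNORECASE)
_RANDOM_RE = re.compile(r"random", re.IGNORECASE)


def parse_subgenome(chrom: str) -> str:
    """Subgenome label ('A', 'C' or 'unplaced') from a chromosome name.

    Handles 'A01'..'A10', 'C01'..'C09' and the unanchored 'Ann_random' /
    'Cnn_random' scaffolds of the B. napus assembly.
    """
    m = _SUBGENOME_RE.match(chrom)
    if m:
        return m.group(1).upper()
    return "unplaced"


def is_random_scaffold(chrom: str) -> bool:
    return bool(_RANDOM_RE.search(chrom))


# ---------------------------------------------------------------------------
# tabular files with a commented metadata header

def write_tsv(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a TSV with '#'-prefixed metadata lines before the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# endoimprint {__version__}\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# GFF3 gene models

def write_gene_models_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene models (gene_id, chrom, start, end, strand) as GFF3."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tendoimprint_sim\tgene\t{row.start}\t{row.end}"
                f"\t.\t{row.strand}\t.\tID={row.gene_id}\n")


def read_gene_models(path) -> pd.DataFrame:
    """Load gene features from GFF3 into a frame with subgenome labels."""
    rows = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start, feat.end,
                     feat.strand or "+"))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    df["subgenome"] = df["chrom"].map(parse_subgenome)
    return df


# ---------------------------------------------------------------------------
# VCF (single-sample, GT/AD/DP) used for the parental variant calls

VCF_FORMAT_HEADER = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
)


def write_parent_vcf(records: pd.DataFrame, path, sample: str,
                     contigs: dict[str, int]) -> None:
    """Write one parental replicate's calls as a single-sample VCF.

    ``records`` columns: chrom, pos, ref, alt, gt ('0/0','1/1','0/1','./.'),
    ad_ref, ad_alt, dp.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=endoimprint_sim\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(VCF_FORMAT_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 f"\t{sample}\n")
        for r in records.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{r.gt}:{r.ad_ref},{r.ad_alt}:{r.dp}\n")


# ---------------------------------------------------------------------------
# BED6 transposable-element annotation

def write_te_bed(tes: pd.DataFrame, path) -> None:
    """Write TE intervals (chrom, start, end 1-based inclusive, family,
    strand) as BED6 with the family in the name column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for r in tes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.family}\t0"
                     f"\t{r.strand}\n")


def read_te_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "family", "score",
                            "strand"],
                     dtype={"chrom": str, "family": str})
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "family",
                                     "strand"])
    df["start"] = df["start"].astype(int) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(int)
    return df[["chrom", "start", "end", "family", "strand"]]
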