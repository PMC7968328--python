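"""Screen per-parent, per-replicate variant calls for diagnostic SNPs.

A diagnostic SNP is a site where the two cultivars are reliably
homozygous for different alleles: each line must show a concordant
homozygous genotype in at least ``min_replicates`` replicates, with no
discordant call in any remaining replicate, every supporting library
must reach ``min_depth`` reads, and the two consensus alleles must
differ.  Indels and multiallelic records are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")


@dataclass(frozen=True)
class VariantObservation:
    """One line x replicate call at one site."""

    chrom: str
    pos: int  # 1-based
    line_id: str
    replicate_id: str
    genotype: str  # hom_ref | het | hom_alt | missing
    ref: str
    alt: str
    depth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass
class ParentalSnp:
    """A retained diagnostic site with per-line support summaries."""

    chrom: str
    pos: int
    allele_line1: str
    allele_line2: str
    gene_id: Optional[str] = None
    n_supporting_replicates_line1: int = 0
    n_supporting_replicates_line2: int = 0
    min_depth_observed: int = 0


def read_variant_observations(vcf_path, line_id: str,
                              replicate_id: str
                              ) -> Iterator[VariantObservation]:
    """Yield single-sample observations from a VCF (GT/DP fields).

    Multiallelic records and indels are skipped with a logged count; the
    VCF is trusted to derive from uniquely mapped reads (upstream
    contract).
    """
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            call = rec.samples[sample]
            gt = call.get("GT")
            depth = call.get("DP") or 0
            if gt is None or None in gt:
                genotype = "missing"
            elif all(a == 0 for a in gt):
                genotype = "hom_ref"
            elif all(a == 1 for a in gt):
                genotype = "hom_alt"
            else:
                genotype = "het"
            yield VariantObservation(rec.chrom, rec.pos, line_id,
                                     replicate_id, genotype, rec.ref,
                                     alts[0], int(depth))
    if skipped:
        logger.info("skipped %d multiallelic/indel records in %s",
                    skipped, vcf_path)


def screen_parental_snps(observations: Iterable[VariantObservation],
                         min_depth: int = 10,
                         min_replicates: int = 2) -> list[ParentalSnp]:
    """Retain sites where the two lines are reliably homozygous for
    different alleles; output sorted by (chrom, pos)."""
    by_site: dict[tuple[str, int], list[VariantObservation]] = {}
    seen: set[tuple[str, str, str, int]] = set()
    lines: list[str] = []
    for obs in observations:
        key = (obs.line_id, obs.replicate_id, obs.chrom, obs.pos)
        if key in seen:
            raise ValueError(
                f"duplicate observation for line={obs.line_id} "
                f"replicate={obs.replicate_id} at {obs.chrom}:{obs.pos}")
        seen.add(key)
        if obs.line_id not in lines:
            lines.append(obs.line_id)
        by_site.setdefault((obs.chrom, obs.pos), []).append(obs)
    if len(lines) != 2:
        raise ValueError(f"expected observations from exactly two lines, "
                         f"got {lines}")
    line1, line2 = lines

    retained: list[ParentalSnp] = []
    for (chrom, pos), site_obs in sorted(by_site.items()):
        consensus: dict[str, str] = {}
        support: dict[str, int] = {}
        min_depth_obs = None
        ok = True
        for line in (line1, line2):
            calls = [o for o in site_obs if o.line_id == line]
            homs = [o for o in calls if o.genotype in ("hom_ref", "hom_alt")]
            discordant = [o for o in calls if o.genotype == "het"]
            if not homs or discordant:
                ok = False
                break
            genotypes = {o.genotype for o in homs}
            if len(genotypes) != 1:  # contradictory homozygous calls
                ok = False
                break
            if len(homs) < min_replicates:
                ok = False
                break
            if any(o.depth < min_depth for o in homs):
                ok = False
                break
            gt = genotypes.pop()
            consensus[line] = homs[0].alt if gt == "hom_alt" else homs[0].ref
            support[line] = len(homs)
            d = min(o.depth for o in homs)
            min_depth_obs = d if min_depth_obs is None else min(min_depth_obs, d)
        if not ok or consensus[line1] == consensus[line2]:
            continue
        retained.append(ParentalSnp(
            chrom=chrom, pos=pos,
            allele_line1=consensus[line1], allele_line2=consensus[line2],
            n_supporting_replicates_line1=support[line1],
            n_supporting_replicates_line2=support[line2],
            min_depth_observed=int(min_depth_obs)))
    return retained


def map_snps_to_genes(snps: list[ParentalSnp],
                      gene_models: pd.DataFrame) -> list[ParentalSnp]:
    """Assign each SNP to every gene whose [start, end] contains it.

    A SNP inside k overlapping genes yields k records (one per gene);
    intergenic SNPs keep gene_id=None.  Interval ends are 1-based
    inclusive.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_models.itertuples(index=False):
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id)
    known_chroms = set(trees)
    warned: set[str] = set()
    out: list[ParentalSnp] = []
    for snp in snps:
        if snp.chrom not in known_chroms:
            if snp.chrom not in warned:
                logger.warning("chromosome %s absent from annotation",
                               snp.chrom)
                warned.add(snp.chrom)
            out.append(ParentalSnp(**{**snp.__dict__, "gene_id": None}))
            continue
        hits = sorted(iv.data for iv in trees[snp.chrom][snp.pos])
        if not hits:
            out.append(ParentalSnp(**{**snp.__dict__, "gene_id": None}))
        else:
            for gid in hits:
                out.append(ParentalSnp(**{**snp.__dict__, "gene_id": gid}))
    return out


def snps_to_frame(snps: list[ParentalSnp]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in snps])


def screen_vcf_files(vcfs_line1: dict[str, str], vcfs_line2: dict[str, str],
                     line1: str, line2: str, min_depth: int = 10,
                     min_replicates: int = 2) -> list[ParentalSnp]:
    """Convenience wrapper: screen from {replicate_id: vcf_path} maps."""
    def _gen():
        for line, vcfs in ((line1, vcfs_line1), (line2, vcfs_line2)):
            for rep, path in vcfs.items():
                yield from read_variant_observations(path, line, rep)
    return screen_parental_snps(_gen(), min_depth=min_depth,
                                min_replicates=min_replicates)
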