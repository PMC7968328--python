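"""Configuration objects for simulation, imprint calling and pipeline runs.

The defaults encode the study design being emulated: two homozygous
*Brassica napus* cultivars crossed reciprocally, three biological
replicates per cross, endosperm sampled at two developmental stages, and
a triploid (2m:1p) allelic dosage null.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, fields
from typing import Optional

import yaml

DEFAULT_STAGES = ("20DAP", "25DAP")
DEFAULT_TISSUES = ("endosperm", "root", "stem", "leaf", "bud")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic reciprocal-cross endosperm dataset.

    Counts are per chromosome / per gene / per library; ``depth_mean`` is
    the expected number of informative reads per gene per library;
    ``overdispersion`` is the beta-binomial intra-class correlation rho
    (0 recovers the plain binomial).
    """

    seed: int = 0
    n_chrom_a: int = 10
    n_chrom_c: int = 9
    genes_per_chrom: int = 100
    chrom_length: int = 20_000_000
    gene_length_range: tuple[int, int] = (800, 4000)
    snps_per_gene: float = 3.0
    depth_mean: float = 60.0
    overdispersion: float = 0.02
    frac_meg: float = 0.05
    frac_peg: float = 0.005
    meg_maternal_frac: float = 0.98
    peg_paternal_frac: float = 0.75
    n_replicates: int = 3
    stages: tuple[str, ...] = DEFAULT_STAGES
    cluster_frac: float = 0.5
    cluster_size_range: tuple[int, int] = (3, 5)
    te_flank_boost: float = 4.0
    te_density_per_kb: float = 0.05
    stage_switch_frac: float = 0.15
    corrupt_frac: float = 0.02
    endosperm_specific_frac: float = 0.1
    line1: str = "ZS11"
    line2: str = "Y6"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("n_chrom_a", "n_chrom_c", "genes_per_chrom",
                     "chrom_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("meg_maternal_frac", "peg_paternal_frac", "frac_meg",
                     "frac_peg", "cluster_frac", "stage_switch_frac",
                     "corrupt_frac", "endosperm_specific_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion (rho) must lie in [0, 1)")
        if self.frac_meg + self.frac_peg >= 1.0:
            raise ValueError("frac_meg + frac_peg must be < 1")
        if self.depth_mean <= 0 or self.snps_per_gene < 1:
            raise ValueError("depth_mean must be > 0 and snps_per_gene >= 1")
        if self.line1 == self.line2:
            raise ValueError("parental lines must be distinct")
        if len(self.stages) != len(set(self.stages)):
            raise ValueError("stage labels must be unique")

    @property
    def chrom_names(self) -> list[str]:
        return [f"A{i:02d}" for i in range(1, self.n_chrom_a + 1)] + \
               [f"C{i:02d}" for i in range(1, self.n_chrom_c + 1)]

    @property
    def n_genes(self) -> int:
        return self.genes_per_chrom * (self.n_chrom_a + self.n_chrom_c)

    @property
    def crosses(self) -> list["CrossDesign"]:
        return [
            CrossDesign(f"{self.line1}x{self.line2}", self.line1, self.line2),
            CrossDesign(f"{self.line2}x{self.line1}", self.line2, self.line1),
        ]


@dataclass(frozen=True)
class CrossDesign:
    """One orientation of the reciprocal cross: mother x father."""

    cross_id: str
    mother: str
    father: str

    def __post_init__(self) -> None:
        if self.mother == self.father:
            raise ValueError("mother and father lines must differ")


@dataclass(frozen=True)
class Design:
    """Full experimental design: lines, reciprocal crosses, stages, replicates."""

    lines: tuple[str, str]
    crosses: tuple[CrossDesign, ...]
    stages: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        mothers = {c.mother for c in self.crosses}
        if len(self.crosses) == 2 and len(mothers) != 2:
            raise ValueError("a reciprocal design needs both orientations")

    @classmethod
    def from_sim_config(cls, cfg: SimConfig) -> "Design":
        return cls(
            lines=(cfg.line1, cfg.line2),
            crosses=tuple(cfg.crosses),
            stages=tuple(cfg.stages),
            replicates=tuple(range(1, cfg.n_replicates + 1)),
        )

    def library_id(self, stage: str, cross_id: str, replicate: int) -> str:
        return f"{stage}_{cross_id}_rep{replicate}"

    def libraries(self) -> dict[str, dict]:
        out = {}
        for stage in self.stages:
            for cross in self.crosses:
                for rep in self.replicates:
                    out[self.library_id(stage, cross.cross_id, rep)] = {
                        "stage": stage,
                        "cross": cross.cross_id,
                        "replicate": rep,
                        "mother": cross.mother,
                        "father": cross.father,
                    }
        return out

    def cross_by_id(self, cross_id: str) -> CrossDesign:
        for c in self.crosses:
            if c.cross_id == cross_id:
                return c
        raise KeyError(f"unknown cross_id {cross_id!r}")

    def to_dict(self) -> dict:
        return {
            "lines": list(self.lines),
            "crosses": [asdict(c) for c in self.crosses],
            "stages": list(self.stages),
            "replicates": list(self.replicates),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Design":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            lines=tuple(d["lines"]),
            crosses=tuple(CrossDesign(**c) for c in d["crosses"]),
            stages=tuple(d["stages"]),
            replicates=tuple(d["replicates"]),
        )


@dataclass(frozen=True)
class ImprintThresholds:
    """Gates for MEG/PEG classification against the 2:1 endosperm null.

    ``meg_min_ratio`` is maternal:paternal (10:1), ``peg_min_ratio`` is
    paternal:maternal (3:2 = 1.5).  Both are applied multiplicatively to
    pooled counts, which avoids division by zero when one parental
    allele is absent.
    """

    null_ratio: tuple[int, int] = (2, 1)
    meg_min_ratio: float = 10.0
    peg_min_ratio: float = 1.5
    q_max: float = 0.05
    min_informative_reads: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.q_max < 1.0:
            raise ValueError("q_max must lie in (0, 1)")
        if self.min_informative_reads < 0:
            raise ValueError("min_informative_reads must be >= 0")
        if min(self.null_ratio) <= 0:
            raise ValueError("null_ratio components must be positive")
        if not (self.meg_min_maternal_frac > self.null_maternal_frac
                > 1.0 - self.peg_min_paternal_frac):
            raise ValueError(
                "MEG bound must exceed the null maternal fraction, which "
                "must exceed 1 - PEG bound")

    @property
    def null_maternal_frac(self) -> float:
        m, p = self.null_ratio
        return m / (m + p)

    @property
    def meg_min_maternal_frac(self) -> float:
        """Maternal-read fraction equivalent of the 10:1 MEG ratio (10/11)."""
        return self.meg_min_ratio / (self.meg_min_ratio + 1.0)

    @property
    def peg_min_paternal_frac(self) -> float:
        """Paternal-read fraction equivalent of the 3:2 PEG ratio (0.6)."""
        return self.peg_min_ratio / (self.peg_min_ratio + 1.0)


def config_hash(obj) -> str:
    """Stable short hash of a dataclass/dict config, for artifact headers."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def sim_config_from_dict(d: dict) -> SimConfig:
    known = {f.name for f in fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
    for name in ("gene_length_range", "cluster_size_range", "stages"):
        if name in d and isinstance(d[name], list):
            d[name] = tuple(d[name])
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return sim_config_from_dict(d)
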