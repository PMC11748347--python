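"""Shared domain types for the prioritization, CNV and QC stages.

Coordinate convention: all internal coordinates are 1-based inclusive
(VCF-style). BED input is converted at the boundary by :mod:`panelprio.io`.
Chromosome names are compared after stripping an optional ``chr`` prefix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


def norm_chrom(chrom: str) -> str:
    """Canonical chromosome name: strip an optional ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"
    HEM = "HEM"


class ClinClass(str, enum.Enum):
    """ACMG/AMP five-tier classes plus CIP (conflicting interpretations)."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    CIP = "CIP"
    LB = "LB"
    B = "B"
    NONE = "NONE"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class CaseMode(str, enum.Enum):
    DIAGNOSTIC = "DIAGNOSTIC"
    CARRIER = "CARRIER"


#: Contigs on which hemizygous male genotypes are legitimate.
NON_AUTOSOMES = {"X", "Y", "MT", "M"}


@dataclass
class GenomicInterval:
    """A labelled 1-based inclusive interval (target, exon, ...)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedVariant:
    """One small-variant call with genotype, quality and annotation fields.

    The atom of the prioritization cascade: one object per ALT allele
    genotyped non-reference in the sample. ``maf`` maps population-frequency
    source names to allele frequencies; an empty map means no database record
    exists (treated as rare downstream, flagged ``NO_FREQUENCY_DATA``).
    ``cip_has_plp`` is only meaningful when ``clin_class`` is CIP and records
    whether at least one submitter called the variant P/LP.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = ""
    zygosity: Zygosity = Zygosity.HET
    vaf: float | None = None
    depth: int | None = None
    maf: dict[str, float] = field(default_factory=dict)
    clin_class: ClinClass = ClinClass.NONE
    cip_has_plp: bool = False
    scores: dict[str, str] = field(default_factory=dict)
    hgvs: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        for src, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"maf[{src}] out of [0,1]: {f}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (norm_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def max_maf(self) -> float | None:
        """Largest frequency over all populated sources, None when absent."""
        return max(self.maf.values()) if self.maf else None

    @property
    def is_autosomal(self) -> bool:
        return norm_chrom(self.chrom) not in NON_AUTOSOMES


@dataclass
class SampleCase:
    """A referral: one sample with its clinical context and ordered panels."""

    sample_id: str
    sex: Sex = Sex.UNKNOWN
    category: str = ""
    panels: list[str] = field(default_factory=list)
    mode: CaseMode = CaseMode.DIAGNOSTIC

    def __post_init__(self) -> None:
        if self.mode is CaseMode.DIAGNOSTIC and not self.panels:
            raise ValueError(
                f"diagnostic case {self.sample_id!r} must name >= 1 panel"
            )


@dataclass
class PedMember:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: bool


@dataclass
class Pedigree:
    """Family structure plus per-member genotypes at variants of interest.

    ``genotypes`` maps member id -> variant key -> Zygosity; a missing entry
    means the member was not genotyped at that variant (reference or unknown).
    """

    members: list[PedMember] = field(default_factory=list)
    genotypes: dict[str, dict[tuple[str, int, str, str], Zygosity]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        ids = {m.sample_id for m in self.members}
        if len(ids) != len(self.members):
            raise ValueError("duplicate sample ids in pedigree")
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise ValueError(
                        f"parent id {pid!r} of {m.sample_id!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            seen: set[str] = set()
            stack = [m.sample_id]
            while stack:
                cur = by_id.get(stack.pop())
                if cur is None:
                    continue
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid == m.sample_id:
                        raise ValueError(
                            f"{m.sample_id!r} is its own ancestor"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def member(self, sample_id: str) -> PedMember | None:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        return None

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        m = self.member(sample_id)
        return (m.father_id, m.mother_id) if m else (None, None)

    def genotype(
        self, sample_id: str, key: tuple[str, int, str, str]
    ) -> Zygosity | None:
        return self.genotypes.get(sample_id, {}).get(key)


@dataclass
class CoverageMatrix:
    """Per-target mean depths across a batch of samples (targets x samples)."""

    targets: list[GenomicInterval]
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.targets), len(self.samples)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.targets)} targets x {len(self.samples)} samples"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depths in coverage matrix")

    def column(self, sample_id: str) -> np.ndarray:
        return self.depth[:, self.samples.index(sample_id)]


class CtRole(str, enum.Enum):
    TARGET = "TARGET"
    REFERENCE = "REFERENCE"


@dataclass
class CtRow:
    sample_id: str
    assay_id: str
    role: CtRole
    calibrator: bool
    ct: float
    replicate: int = 1


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements for the 2^-ddCt calculator."""

    rows: list[CtRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows and not any(r.calibrator for r in self.rows):
            raise ValueError("Ct table contains no calibrator sample")
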