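"""Core value types shared across the pipeline.

Coordinates are 1-based and fully closed throughout, matching VCF.
Multi-allelic records are decomposed into biallelic sites before any of
these types are constructed.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

_BASES = frozenset("ACGT")


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemizygous_ref"
    HEMI_ALT = "hemizygous_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic variant: chrom, 1-based pos of the first ref base, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not _BASES.issuperset(allele):
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def length_change(self) -> int:
        """alt length minus ref length; negative for deletions."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleCall:
    """Genotype plus read support for one sample at one site."""

    genotype: Genotype
    depth: int
    alt_reads: int
    ref_reads: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.alt_reads + self.ref_reads > self.depth:
            raise ValueError("alt_reads + ref_reads must not exceed depth")

    @property
    def vaf(self) -> Optional[float]:
        """Variant allele fraction; None when no reads cover the site."""
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class TrioCall:
    """One variant site observed jointly in proband, father and mother."""

    site: VariantSite
    proband: SampleCall
    father: SampleCall
    mother: SampleCall
    proband_sex: str = "F"  # {M, F}
    trio_id: str = "trio"

    def __post_init__(self) -> None:
        if self.proband_sex not in ("M", "F"):
            raise ValueError("proband_sex must be 'M' or 'F'")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant annotation: gene, transcript, predictor scores, frequencies.

    Absent predictor scores are ``None``.  ``panel_afs`` maps population-panel
    names (e.g. ``1000g``, ``evs``) to allele frequencies; a variant absent
    from a panel simply lacks the key (treated as frequency 0).
    """

    site: VariantSite
    gene: str
    transcript_id: str = ""
    sift: Optional[float] = None
    polyphen2: Optional[float] = None
    provean: Optional[float] = None
    panel_afs: Mapping[str, float] = field(default_factory=dict)
    inhouse_carrier_fraction: float = 0.0
    splice_prediction_flag: bool = False

    def __post_init__(self) -> None:
        for name, af in self.panel_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"panel {name} AF {af} outside [0, 1]")
        if not 0.0 <= self.inhouse_carrier_fraction <= 1.0:
            raise ValueError("inhouse_carrier_fraction outside [0, 1]")


class GeneTier(str, enum.Enum):
    KNOWN_ID = "known_id"
    CANDIDATE_ID = "candidate_id"
    RECESSIVE_OR_XLINKED_ID = "recessive_or_xlinked_id"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols with a diagnostic tier."""

    name: str
    genes: frozenset[str]
    tier: GeneTier

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


X_CHROM_NAMES = frozenset({"X", "chrX"})


def is_x_chromosome(chrom: str) -> bool:
    return chrom in X_CHROM_NAMES
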