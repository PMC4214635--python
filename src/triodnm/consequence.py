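"""Variant consequence classification, LoF and damaging-prediction rules.

Classes follow the taxonomy used in trio DNM burden studies: coding SNVs
split into missense / synonymous / nonsense, splice-site SNVs into the
canonical dinucleotides (acceptor -1/-2, donor +1/+2) versus the wider
consensus window (acceptor -3, donor +3..+6), and coding indels into
frameshift versus in-frame.  Every variant receives exactly one class;
splice classes apply only to intronic positions, so a coding base that also
sits near an exon boundary is classified by its coding effect (synonymous
changes there are tagged ``splice_region_synonymous``).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .transcripts import TranscriptModel, reverse_complement
from .types import AnnotationRecord, GenePanel, GeneTier, VariantSite

# Standard genetic code (NCBI translation table 1), '*' = stop.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    CANONICAL_SPLICE = "canonical_splice"
    CONSENSUS_SPLICE = "consensus_splice"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    SPLICE_REGION_SYNONYMOUS = "splice_region_synonymous"
    NONCODING = "noncoding"


#: Coding-SNV classes entering the per-base rate and burden denominators.
CODING_SNV_CLASSES = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.SYNONYMOUS,
        ConsequenceClass.SPLICE_REGION_SYNONYMOUS,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.CANONICAL_SPLICE,
    }
)


def _affected_positions(site: VariantSite) -> list[int]:
    """Genomic positions whose identity the variant changes.

    SNV: the site itself.  Deletions (anchored, ref[0]==alt[0]): the deleted
    bases.  Insertions: the two flanking bases of the insertion point.
    """
    if site.is_snv:
        return [site.pos]
    if len(site.ref) > len(site.alt) and site.ref.startswith(site.alt):
        return list(range(site.pos + len(site.alt), site.pos + len(site.ref)))
    if len(site.alt) > len(site.ref) and site.alt.startswith(site.ref):
        return [site.pos + len(site.ref) - 1, site.pos + len(site.ref)]
    # complex substitution: the whole ref footprint
    return list(range(site.pos, site.pos + len(site.ref)))


def classify(site: VariantSite, model: TranscriptModel) -> ConsequenceClass:
    """Assign exactly one consequence class to ``site`` against ``model``.

    Priority: canonical splice (intronic -1/-2, +1/+2), then consensus
    splice (intronic -3 / +3..+6), then coding indel (frameshift vs
    in-frame by length mod 3), then coding SNV (nonsense / synonymous /
    missense via codon translation), else noncoding.
    """
    if site.chrom != model.chrom:
        return ConsequenceClass.NONCODING
    positions = _affected_positions(site)
    if positions[-1] > len(model.contig_seq):
        raise ValueError(f"site {site} outside contig {model.chrom}")

    intronic = [p for p in positions if model.is_intronic(p)]
    if intronic:
        canonical = model.canonical_splice_positions()
        if any(p in canonical for p in intronic):
            return ConsequenceClass.CANONICAL_SPLICE
        consensus = model.consensus_splice_positions()
        if any(p in consensus for p in intronic):
            return ConsequenceClass.CONSENSUS_SPLICE

    coding = [p for p in positions if model.in_cds(p)]
    if not coding:
        return ConsequenceClass.NONCODING

    if site.is_indel:
        delta = site.length_change
        if delta == 0:  # length-preserving substitution block
            return ConsequenceClass.MISSENSE
        if delta > 0:
            return (
                ConsequenceClass.INFRAME_INSERTION
                if delta % 3 == 0
                else ConsequenceClass.FRAMESHIFT_INSERTION
            )
        return (
            ConsequenceClass.INFRAME_DELETION
            if delta % 3 == 0
            else ConsequenceClass.FRAMESHIFT_DELETION
        )

    return _classify_coding_snv(site, model)


def _classify_coding_snv(site: VariantSite, model: TranscriptModel) -> ConsequenceClass:
    idx = model.cds_index(site.pos)
    cds = model.cds_sequence()
    codon_start = (idx // 3) * 3
    old_codon = cds[codon_start : codon_start + 3]
    alt_base = site.alt if model.strand == "+" else reverse_complement(site.alt)
    within = idx % 3
    new_codon = old_codon[:within] + alt_base + old_codon[within + 1 :]
    old_aa, new_aa = GENETIC_CODE[old_codon], GENETIC_CODE[new_codon]
    if new_aa == "*" and old_aa != "*":
        return ConsequenceClass.NONSENSE
    if new_aa == old_aa:
        if site.pos in model.splice_region_exonic_positions():
            return ConsequenceClass.SPLICE_REGION_SYNONYMOUS
        return ConsequenceClass.SYNONYMOUS
    # stop-loss and start-loss fold into missense
    return ConsequenceClass.MISSENSE


def classify_worst(site: VariantSite, models: Iterable[TranscriptModel]) -> ConsequenceClass:
    """Worst consequence of ``site`` across transcript models on its contig."""
    severity = {
        ConsequenceClass.NONSENSE: 0,
        ConsequenceClass.FRAMESHIFT_DELETION: 1,
        ConsequenceClass.FRAMESHIFT_INSERTION: 1,
        ConsequenceClass.CANONICAL_SPLICE: 2,
        ConsequenceClass.CONSENSUS_SPLICE: 3,
        ConsequenceClass.INFRAME_DELETION: 4,
        ConsequenceClass.INFRAME_INSERTION: 4,
        ConsequenceClass.MISSENSE: 5,
        ConsequenceClass.SPLICE_REGION_SYNONYMOUS: 6,
        ConsequenceClass.SYNONYMOUS: 7,
        ConsequenceClass.NONCODING: 8,
    }
    classes = [classify(site, m) for m in models if m.chrom == site.chrom]
    if not classes:
        return ConsequenceClass.NONCODING
    return min(classes, key=severity.__getitem__)


def is_lof_snv(cls: ConsequenceClass) -> bool:
    """LoF-SNV membership for the burden test: nonsense + canonical splice.

    Frameshifts are loss-of-function but not single-nucleotide events, and
    consensus-splice variants are excluded from the SNV totals, so neither
    counts here.
    """
    return cls in (ConsequenceClass.NONSENSE, ConsequenceClass.CANONICAL_SPLICE)


TRUNCATING_CLASSES = frozenset(
    {
        ConsequenceClass.NONSENSE,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT_INSERTION,
        ConsequenceClass.FRAMESHIFT_DELETION,
    }
)


@dataclass(frozen=True)
class DamagingCriteria:
    """Thresholds for calling a variant predicted-damaging.

    Defaults follow the predictors' published conventions: SIFT <= 0.05,
    PolyPhen-2 >= 0.45, PROVEAN <= -2.5.  For missense variants every
    available predictor must call damaging; inframe indels are judged by
    PROVEAN alone.
    """

    sift_max: float = 0.05
    polyphen2_min: float = 0.45
    provean_max: float = -2.5


def is_predicted_damaging(
    ann: Optional[AnnotationRecord],
    cls: ConsequenceClass,
    crit: DamagingCriteria = DamagingCriteria(),
) -> bool:
    """Apply the damaging-prediction rule for one classified variant.

    Truncating classes are damaging by definition.  Missense requires all
    available predictor scores to agree (no scores -> not damaging).
    Synonymous is damaging only when in the splice region with an external
    splice-prediction flag set.
    """
    if cls in TRUNCATING_CLASSES:
        return True
    if cls in (ConsequenceClass.SYNONYMOUS, ConsequenceClass.SPLICE_REGION_SYNONYMOUS):
        return (
            cls is ConsequenceClass.SPLICE_REGION_SYNONYMOUS
            and ann is not None
            and ann.splice_prediction_flag
        )
    if cls is ConsequenceClass.NONCODING:
        return False
    if ann is None:
        return False
    if cls is ConsequenceClass.MISSENSE:
        scores = [
            (ann.sift, lambda v: v <= crit.sift_max),
            (ann.polyphen2, lambda v: v >= crit.polyphen2_min),
            (ann.provean, lambda v: v <= crit.provean_max),
        ]
        available = [(v, ok) for v, ok in scores if v is not None]
        if not available:
            return False  # unscored
        return all(ok(v) for v, ok in available)
    if cls in (ConsequenceClass.INFRAME_INSERTION, ConsequenceClass.INFRAME_DELETION):
        return ann.provean is not None and ann.provean <= crit.provean_max
    if cls is ConsequenceClass.CONSENSUS_SPLICE:
        return True  # splice-disrupting by position
    return False


def assign_gene_tier(gene: str, panels: Sequence[GenePanel]) -> GeneTier:
    """Tier a gene: known-ID panel first, then candidate, else unknown."""
    for tier in (GeneTier.KNOWN_ID, GeneTier.CANDIDATE_ID):
        for panel in panels:
            if panel.tier is tier and gene in panel:
                return tier
    return GeneTier.UNKNOWN
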