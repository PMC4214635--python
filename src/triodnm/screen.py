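"""Screen for rare inherited candidate genotypes in recessive/X-linked panels.

Three mechanisms qualify: a male proband hemizygous for a maternal
X-chromosome variant, a homozygote with both parents heterozygous, and a
compound heterozygote carrying two variants of the same gene in trans (one
from each parent, resolved from parental genotypes alone — pairs that
cannot be phased that way are excluded).  Variants must be rare and
predicted damaging, and the gene must belong to a recessive/X-linked
disease panel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .consequence import (
    ConsequenceClass,
    DamagingCriteria,
    classify_worst,
    is_predicted_damaging,
)
from .filters import FilterConfig, is_rare, passes_site_support
from .transcripts import TranscriptModel
from .types import (
    AnnotationRecord,
    GenePanel,
    Genotype,
    GeneTier,
    TrioCall,
    VariantSite,
    is_x_chromosome,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PARConfig:
    """X pseudo-autosomal intervals, treated as autosomal in the screen."""

    intervals: tuple[tuple[int, int], ...] = ()

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


@dataclass(frozen=True)
class InheritedCandidate:
    trio_id: str
    gene: str
    mechanism: str  # {hemizygous_x, homozygous, compound_het}
    variants: tuple[tuple[VariantSite, str], ...]  # (site, parental origin)
    predicted_damaging: bool = True

    def __post_init__(self) -> None:
        if self.mechanism == "compound_het":
            if len(self.variants) != 2:
                raise ValueError("compound_het needs exactly two variants")
            origins = {origin for _, origin in self.variants}
            if origins != {"father", "mother"}:
                raise ValueError("compound_het variants must be in trans")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.mechanism} carries exactly one variant")


def _qualifies(
    trio: TrioCall,
    ann: Optional[AnnotationRecord],
    models: Mapping[str, Sequence[TranscriptModel]],
    cfg: FilterConfig,
    crit: DamagingCriteria,
) -> bool:
    """Rare + supported + predicted-damaging pre-filter for screen variants."""
    if not passes_site_support(trio.proband, cfg):
        return False
    if not is_rare(ann, cfg):
        return False
    if ann is None:
        return False
    chrom_models = models.get(trio.site.chrom, ())
    if not chrom_models:
        # annotation-driven mode: no transcript models available, judge by
        # predictor scores as for a missense change
        cls = ConsequenceClass.MISSENSE
    else:
        cls = classify_worst(trio.site, chrom_models)
    return is_predicted_damaging(ann, cls, crit)


def find_inherited_candidates(
    trios: Iterable[TrioCall],
    annotations: Mapping[tuple, AnnotationRecord],
    panels: Sequence[GenePanel],
    models: Sequence[TranscriptModel] = (),
    cfg: FilterConfig = FilterConfig(),
    crit: DamagingCriteria = DamagingCriteria(),
    par: PARConfig = PARConfig(),
) -> list[InheritedCandidate]:
    """Emit Mendelianly consistent recessive/X-linked candidate genotypes.

    Only genes present in a panel with tier ``recessive_or_xlinked_id`` are
    considered.  Compound-het pairs whose trans configuration cannot be
    established from parental genotypes (either variant untyped in a
    parent, or both inherited from the same parent) are excluded.
    """
    panel_genes: set[str] = set()
    for panel in panels:
        if panel.tier is GeneTier.RECESSIVE_OR_XLINKED_ID:
            panel_genes |= panel.genes
    if not panel_genes:
        return []

    models_by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        models_by_chrom.setdefault(m.chrom, []).append(m)

    out: list[InheritedCandidate] = []
    het_by_trio_gene: dict[tuple[str, str], list[TrioCall]] = {}

    for trio in trios:
        ann = annotations.get(trio.site.key)
        if ann is None or ann.gene not in panel_genes:
            continue
        if not _qualifies(trio, ann, models_by_chrom, cfg, crit):
            continue
        gt = trio.proband.genotype
        x_linked = is_x_chromosome(trio.site.chrom) and not par.contains(trio.site.pos)

        if (
            x_linked
            and trio.proband_sex == "M"
            and gt in (Genotype.HEMI_ALT, Genotype.HOM_ALT)
            and trio.mother.genotype is Genotype.HET
            and trio.father.genotype in (Genotype.HEMI_REF, Genotype.HOM_REF)
        ):
            out.append(
                InheritedCandidate(
                    trio_id=trio.trio_id,
                    gene=ann.gene,
                    mechanism="hemizygous_x",
                    variants=((trio.site, "mother"),),
                )
            )
        elif (
            not x_linked
            and gt is Genotype.HOM_ALT
            and trio.father.genotype is Genotype.HET
            and trio.mother.genotype is Genotype.HET
        ):
            out.append(
                InheritedCandidate(
                    trio_id=trio.trio_id,
                    gene=ann.gene,
                    mechanism="homozygous",
                    variants=((trio.site, "both"),),
                )
            )
        elif not x_linked and gt is Genotype.HET:
            het_by_trio_gene.setdefault((trio.trio_id, ann.gene), []).append(trio)

    # compound heterozygotes: two hets in one gene, one from each parent
    for (trio_id, gene), hets in sorted(het_by_trio_gene.items()):
        paternal = [t for t in hets if _single_origin(t) == "father"]
        maternal = [t for t in hets if _single_origin(t) == "mother"]
        excluded = len(hets) - len(paternal) - len(maternal)
        if excluded:
            logger.info(
                "screen: %d unphasable het(s) in %s/%s excluded", excluded, trio_id, gene
            )
        for pt in paternal:
            for mt in maternal:
                out.append(
                    InheritedCandidate(
                        trio_id=trio_id,
                        gene=gene,
                        mechanism="compound_het",
                        variants=((pt.site, "father"), (mt.site, "mother")),
                    )
                )
    out.sort(key=lambda c: (c.trio_id, c.gene, c.mechanism))
    return out


def _single_origin(trio: TrioCall) -> Optional[str]:
    """Which parent a proband het was inherited from, by genotype alone.

    Returns None when the origin is ambiguous (both parents carriers, or
    either parent untyped/uncovered) — such variants cannot anchor a trans
    pair.
    """
    fa, mo = trio.father.genotype, trio.mother.genotype
    if fa is Genotype.MISSING or mo is Genotype.MISSING:
        return None
    if fa.carries_alt and not mo.carries_alt:
        return "father"
    if mo.carries_alt and not fa.carries_alt:
        return "mother"
    return None
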