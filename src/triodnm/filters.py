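"""The de novo filter cascade.

Candidate DNMs are trio calls where the proband carries the alternate
allele with solid read support (depth >= 10, >= 4 alt reads making up
>= 20% of reads), the variant is rare in population panels and in-house
exomes (< 0.5%), and neither parent shows evidence of carrying it.
Parental absence is deliberately not "zero alt reads": a lone stray read
in a deeply covered parent is sequencing noise, so the defaults tolerate
up to 1 alt read at <= 3% VAF; a strict-zero preset is available.

Proband VAF below 25% does not exclude a call — it raises a mosaic flag,
since a germline heterozygote is expected near 50% and a markedly lower
fraction suggests post-zygotic origin.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .consequence import ConsequenceClass
from .types import AnnotationRecord, Genotype, GeneTier, SampleCall, TrioCall, VariantSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the site-support, rarity and parental-absence filters."""

    min_depth: int = 10
    min_alt_reads: int = 4
    min_vaf: float = 0.20
    max_panel_af: float = 0.005
    max_inhouse_fraction: float = 0.005
    mosaic_vaf_threshold: float = 0.25
    max_parent_alt_reads: int = 1
    max_parent_vaf: float = 0.03
    require_parent_depth: int = 10

    def __post_init__(self) -> None:
        for name in ("min_vaf", "max_panel_af", "max_inhouse_fraction",
                     "mosaic_vaf_threshold", "max_parent_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @classmethod
    def strict_parental_zero(cls, **kwargs) -> "FilterConfig":
        """Preset where any parental alt read vetoes the de novo call."""
        return cls(max_parent_alt_reads=0, max_parent_vaf=0.0, **kwargs)


@dataclass(frozen=True)
class DNMRecord:
    """A variant that survived the de novo filter cascade."""

    trio_id: str
    site: VariantSite
    proband_call: SampleCall
    consequence: Optional[ConsequenceClass] = None
    mosaic_flag: bool = False
    predicted_damaging: bool = False
    gene: str = "unknown"
    gene_tier: GeneTier = GeneTier.UNKNOWN
    unannotated: bool = False


def passes_site_support(call: SampleCall, cfg: FilterConfig) -> bool:
    """Depth >= min_depth, alt reads >= min_alt_reads and VAF >= min_vaf."""
    if call.depth < cfg.min_depth or call.depth == 0:
        return False
    if call.alt_reads < cfg.min_alt_reads:
        return False
    return call.alt_reads / call.depth >= cfg.min_vaf


def is_rare(ann: Optional[AnnotationRecord], cfg: FilterConfig) -> bool:
    """Every panel AF and the in-house carrier fraction below the cutoffs.

    A variant absent from all panels (or unannotated) counts as frequency 0.
    """
    if ann is None:
        return True
    if any(af >= cfg.max_panel_af for af in ann.panel_afs.values()):
        return False
    return ann.inhouse_carrier_fraction < cfg.max_inhouse_fraction


def _parent_clear(parent: SampleCall, cfg: FilterConfig) -> bool:
    """True when a parent's data positively excludes carrying the allele."""
    if parent.genotype is Genotype.MISSING:
        return False  # uninformative
    if parent.genotype.carries_alt:
        return False
    if parent.depth < cfg.require_parent_depth:
        return False  # an uncovered parent cannot exclude inheritance
    if parent.alt_reads > cfg.max_parent_alt_reads:
        return False
    vaf = parent.vaf
    return vaf is not None and vaf <= cfg.max_parent_vaf


def is_de_novo(trio: TrioCall, cfg: FilterConfig) -> bool:
    """Proband carries the allele with support; both parents exclude it."""
    if not trio.proband.genotype.carries_alt:
        return False
    if not passes_site_support(trio.proband, cfg):
        return False
    return _parent_clear(trio.father, cfg) and _parent_clear(trio.mother, cfg)


def extract_dnms(
    trios: Iterable[TrioCall],
    annotations: Mapping[tuple, AnnotationRecord] | None,
    cfg: FilterConfig = FilterConfig(),
) -> list[DNMRecord]:
    """Run the full cascade and return DNM records sorted by (trio, chrom, pos).

    ``annotations`` maps ``(chrom, pos, ref, alt)`` to
    :class:`AnnotationRecord`; unannotated sites are retained with
    ``gene='unknown'`` and flagged.  Per-filter exclusion counts are logged.
    """
    annotations = annotations or {}
    counts = {"input": 0, "support": 0, "common": 0, "not_de_novo": 0, "kept": 0}
    out: list[DNMRecord] = []
    for trio in trios:
        counts["input"] += 1
        if not trio.proband.genotype.carries_alt or not passes_site_support(
            trio.proband, cfg
        ):
            counts["support"] += 1
            continue
        ann = annotations.get(trio.site.key)
        if not is_rare(ann, cfg):
            counts["common"] += 1
            continue
        if not is_de_novo(trio, cfg):
            counts["not_de_novo"] += 1
            continue
        vaf = trio.proband.vaf or 0.0
        out.append(
            DNMRecord(
                trio_id=trio.trio_id,
                site=trio.site,
                proband_call=trio.proband,
                mosaic_flag=vaf < cfg.mosaic_vaf_threshold,
                gene=ann.gene if ann is not None else "unknown",
                unannotated=ann is None,
            )
        )
        counts["kept"] += 1
    logger.info(
        "extract_dnms: %(input)d calls in, %(support)d failed support, "
        "%(common)d common, %(not_de_novo)d not de novo, %(kept)d DNMs",
        counts,
    )
    out.sort(key=lambda r: (r.trio_id, r.site.chrom, r.site.pos, r.site.ref, r.site.alt))
    return out


def annotate_records(
    records: Sequence[DNMRecord],
    classify_fn,
    panels,
    damaging_fn,
    annotations: Mapping[tuple, AnnotationRecord] | None = None,
) -> list[DNMRecord]:
    """Fill consequence, gene tier and damaging flag on extracted records.

    ``classify_fn`` maps a :class:`VariantSite` to a
    :class:`ConsequenceClass`; ``damaging_fn`` maps
    ``(annotation, consequence)`` to a boolean.
    """
    from .consequence import assign_gene_tier

    annotations = annotations or {}
    out = []
    for rec in records:
        cls = classify_fn(rec.site)
        ann = annotations.get(rec.site.key)
        out.append(
            replace(
                rec,
                consequence=cls,
                gene_tier=assign_gene_tier(rec.gene, panels),
                predicted_damaging=damaging_fn(ann, cls),
            )
        )
    return out
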