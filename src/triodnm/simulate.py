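"""Seeded simulator of trio exome cohorts with known ground truth.

The generator emulates the data regime a trio exome study sees after
genotype calling: inherited variants segregating at population allele
frequencies and transmitted by Mendelian rules, de novo mutations planted
at a configurable per-base per-generation rate, read depths drawn from a
negative binomial (median ~135x, the depth regime of high-coverage capture
sequencing), allele fractions from binomial read sampling, and three
families of contaminating artifacts that the filter cascade must remove:

(a) apparent Mendelian violations where a parent in fact shows alt reads,
(b) proband calls with weak support (< 4 alt reads or < 20% VAF),
(c) common variants (panel AF >= 0.5%) mis-called as violations.

The genome is a toy: a ~1 Mb set of contigs carrying multi-exon genes, with
the mutation rate scaled up so expected DNM counts per trio are testable in
seconds.  The study-scale regime (mu ~ 1.65-2.6e-8 over ~6e7 callable
bases per proband) is available as a preset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .consequence import ConsequenceClass, classify
from .io import (
    Pedigree,
    write_annotation_table,
    write_callable_summary,
    write_fasta,
    write_transcript_gff3,
    write_trio_vcf,
)
from .transcripts import TranscriptModel
from .types import AnnotationRecord, Genotype, SampleCall, TrioCall, VariantSite

_BASES = "ACGT"

#: expected human germline point-mutation rate and control-study estimates,
#: selectable as ``mu_dnm`` for study-scale simulations
POPULATION_RATE = 1.65e-8
CONTROL_STUDY_RATES = (1.28e-8, 1.51e-8)

DEFAULT_CLASS_MIXTURE: dict[ConsequenceClass, float] = {
    ConsequenceClass.MISSENSE: 0.55,
    ConsequenceClass.SYNONYMOUS: 0.18,
    ConsequenceClass.NONSENSE: 0.06,
    ConsequenceClass.CANONICAL_SPLICE: 0.03,
    ConsequenceClass.CONSENSUS_SPLICE: 0.02,
    ConsequenceClass.FRAMESHIFT_DELETION: 0.08,
    ConsequenceClass.FRAMESHIFT_INSERTION: 0.04,
    ConsequenceClass.INFRAME_DELETION: 0.02,
    ConsequenceClass.INFRAME_INSERTION: 0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    ``mu_dnm`` is the per-base per-generation DNM rate over callable coding
    bases; the toy default is scaled up so that a ~20 kb toy exome yields a
    few DNMs per trio.  ``ccds_length`` defaults to the toy genome's coding
    size when left at 0.
    """

    n_trios: int = 20
    mu_dnm: float = 1.2e-4
    callable_fraction: float = 0.95
    ccds_length: int = 0
    class_mixture: Mapping[ConsequenceClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    n_inherited_per_trio: float = 12.0
    common_af_weight: float = 0.35
    depth_mean: float = 135.0
    depth_overdispersion: Optional[float] = 4.0
    error_rate_parent_alt: float = 0.001
    mosaic_fraction: float = 0.08
    artifact_rate_per_type: float = 0.5
    damaging_missense_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_dnm < 0:
            raise ValueError("mu_dnm must be >= 0")
        if not 0.0 <= self.callable_fraction <= 1.0:
            raise ValueError("callable_fraction outside [0, 1]")
        total = sum(self.class_mixture.values())
        if self.class_mixture and not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"class_mixture sums to {total}, not 1")

    @classmethod
    def noise_free(cls, **kwargs) -> "SimConfig":
        """Zero parental noise, no mosaics, no artifacts, uniform deep coverage."""
        kwargs.setdefault("error_rate_parent_alt", 0.0)
        kwargs.setdefault("mosaic_fraction", 0.0)
        kwargs.setdefault("artifact_rate_per_type", 0.0)
        kwargs.setdefault("depth_overdispersion", None)
        kwargs.setdefault("callable_fraction", 1.0)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What was planted, for scoring the pipeline against."""

    planted_dnms: list[tuple[str, VariantSite, ConsequenceClass, float]] = field(
        default_factory=list
    )
    inherited: list[tuple[str, VariantSite, str]] = field(default_factory=list)
    artifacts: list[tuple[str, VariantSite, str]] = field(default_factory=list)

    def planted_sites(self, trio_id: str) -> set[VariantSite]:
        return {s for t, s, _, _ in self.planted_dnms if t == trio_id}


# --------------------------------------------------------------------------
# toy genome
# --------------------------------------------------------------------------


def _make_gene(
    rng: np.random.Generator, chrom: str, start: int, gene: str, strand: str
) -> tuple[list[tuple[int, int]], int]:
    """Lay out one gene's exons from ``start``; returns (exons, next free pos)."""
    n_exons = int(rng.integers(3, 6))
    exons = []
    pos = start
    total = 0
    for i in range(n_exons):
        exon_len = int(rng.integers(90, 220))
        exons.append((pos, pos + exon_len - 1))
        total += exon_len
        pos += exon_len
        if i < n_exons - 1:
            pos += int(rng.integers(30, 200))  # intron, long enough for windows
    # trim the last exon so the CDS length is divisible by 3
    rem = total % 3
    if rem:
        s, e = exons[-1]
        exons[-1] = (s, e - rem)
        pos -= rem
    return exons, pos + int(rng.integers(400, 900))


def make_toy_genome(
    seed: int = 0,
    genes_per_autosome: int = 10,
    genes_on_x: int = 3,
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Build a deterministic toy reference plus multi-exon transcript models."""
    rng = np.random.default_rng([seed, 7919])
    contig_genes = {"chr1": genes_per_autosome, "chrX": genes_on_x}
    contigs: dict[str, str] = {}
    models: list[TranscriptModel] = []
    gene_no = 0
    for chrom, n_genes in contig_genes.items():
        layouts = []
        pos = 200
        for g in range(n_genes):
            strand = "+" if gene_no % 2 == 0 else "-"
            exons, pos = _make_gene(rng, chrom, pos, f"GENE{gene_no:03d}", strand)
            layouts.append((f"GENE{gene_no:03d}", strand, exons))
            gene_no += 1
        length = pos + 200
        seq = "".join(rng.choice(list(_BASES), size=length))
        contigs[chrom] = seq
        for gene, strand, exons in layouts:
            models.append(
                TranscriptModel(
                    gene=gene,
                    transcript_id=f"{gene}.t1",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=exons[0][0],
                    cds_end=exons[-1][1],
                    contig_seq=seq,
                )
            )
    return contigs, models


# --------------------------------------------------------------------------
# planting variants of a requested consequence class
# --------------------------------------------------------------------------


class PlantingError(ValueError):
    """The requested class cannot be hosted on the given transcript."""


def _random_snv_at(model: TranscriptModel, pos: int, rng: np.random.Generator) -> VariantSite:
    ref = model.fetch(pos, pos)
    alt = _BASES[int(rng.integers(0, 4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(0, 4))]
    return VariantSite(model.chrom, pos, ref, alt)


def plant_consequence(
    model: TranscriptModel,
    cls: ConsequenceClass,
    rng: np.random.Generator,
    max_attempts: int = 4000,
) -> VariantSite:
    """Construct a variant that the classifier assigns exactly ``cls``.

    Raises :class:`PlantingError` when the transcript cannot host the class
    (e.g. canonical splice on a single-exon transcript).
    """
    if cls in (ConsequenceClass.CANONICAL_SPLICE, ConsequenceClass.CONSENSUS_SPLICE):
        if not model.introns:
            raise PlantingError(f"{cls.value} impossible: single-exon transcript")
        if cls is ConsequenceClass.CANONICAL_SPLICE:
            positions = sorted(model.canonical_splice_positions())
        else:
            positions = sorted(
                model.consensus_splice_positions() - model.canonical_splice_positions()
            )
        if not positions:
            raise PlantingError(f"no {cls.value} positions on {model.transcript_id}")
        pos = int(rng.choice(positions))
        site = _random_snv_at(model, pos, rng)
        assert classify(site, model) is cls
        return site

    coding = model.coding_genomic_positions()
    if cls in (
        ConsequenceClass.FRAMESHIFT_DELETION,
        ConsequenceClass.FRAMESHIFT_INSERTION,
        ConsequenceClass.INFRAME_DELETION,
        ConsequenceClass.INFRAME_INSERTION,
    ):
        deletion = cls in (
            ConsequenceClass.FRAMESHIFT_DELETION,
            ConsequenceClass.INFRAME_DELETION,
        )
        inframe = cls in (
            ConsequenceClass.INFRAME_DELETION,
            ConsequenceClass.INFRAME_INSERTION,
        )
        length = 3 if inframe else int(rng.integers(1, 3))
        coding_set = set(coding)
        for _ in range(max_attempts):
            anchor = int(rng.choice(coding))
            if deletion:
                affected = range(anchor + 1, anchor + 1 + length)
                if not all(p in coding_set for p in affected):
                    continue
                ref = model.fetch(anchor, anchor + length)
                site = VariantSite(model.chrom, anchor, ref, ref[0])
            else:
                if anchor + 1 not in coding_set:
                    continue
                ref = model.fetch(anchor, anchor)
                ins = "".join(rng.choice(list(_BASES), size=length))
                site = VariantSite(model.chrom, anchor, ref, ref + ins)
            if classify(site, model) is cls:
                return site
        raise PlantingError(f"could not place {cls.value} on {model.transcript_id}")

    if cls in (
        ConsequenceClass.MISSENSE,
        ConsequenceClass.SYNONYMOUS,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.SPLICE_REGION_SYNONYMOUS,
    ):
        for _ in range(max_attempts):
            pos = int(rng.choice(coding))
            site = _random_snv_at(model, pos, rng)
            if classify(site, model) is cls:
                return site
        raise PlantingError(f"could not place {cls.value} on {model.transcript_id}")

    raise PlantingError(f"cannot plant class {cls.value}")


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_cohort`, with file writers."""

    config: SimConfig
    reference: dict[str, str]
    models: list[TranscriptModel]
    pedigrees: list[Pedigree]
    trio_calls: dict[str, list[TrioCall]]
    annotations: dict[tuple, AnnotationRecord]
    callable_bases: dict[str, int]
    truth: GroundTruth

    @property
    def all_calls(self) -> list[TrioCall]:
        return [c for calls in self.trio_calls.values() for c in calls]

    @property
    def total_callable_bases(self) -> int:
        return sum(self.callable_bases.values())

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write reference, transcripts, per-trio VCFs, annotations and truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        contig_lengths = {c: len(s) for c, s in self.reference.items()}
        paths["fasta"] = outdir / "reference.fa"
        write_fasta(paths["fasta"], self.reference)
        paths["gff3"] = outdir / "transcripts.gff3"
        write_transcript_gff3(paths["gff3"], self.models)
        paths["annotations"] = outdir / "annotations.tsv"
        write_annotation_table(paths["annotations"], self.annotations.values())
        paths["callable"] = outdir / "callable.tsv"
        write_callable_summary(paths["callable"], self.callable_bases)
        for ped in self.pedigrees:
            vcf_path = outdir / f"{ped.trio_id}.vcf"
            write_trio_vcf(vcf_path, self.trio_calls[ped.trio_id], ped, contig_lengths)
            ped_path = outdir / f"{ped.trio_id}.ped"
            sex_code = "1" if ped.proband_sex == "M" else "2"
            ped_path.write_text(
                f"{ped.trio_id}\t{ped.proband}\t{ped.father}\t{ped.mother}\t{sex_code}\t2\n"
                f"{ped.trio_id}\t{ped.father}\t0\t0\t1\t1\n"
                f"{ped.trio_id}\t{ped.mother}\t0\t0\t2\t1\n"
            )
            paths[f"vcf:{ped.trio_id}"] = vcf_path
            paths[f"ped:{ped.trio_id}"] = ped_path
        truth_lines = ["trio_id\tchrom\tpos\tref\talt\tcategory\tdetail"]
        for t, s, cls, vaf in self.truth.planted_dnms:
            truth_lines.append(
                f"{t}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\tdnm\t{cls.value}:{vaf:.3f}"
            )
        for t, s, parent in self.truth.inherited:
            truth_lines.append(
                f"{t}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\tinherited\t{parent}"
            )
        for t, s, reason in self.truth.artifacts:
            truth_lines.append(
                f"{t}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\tartifact\t{reason}"
            )
        paths["truth"] = outdir / "ground_truth.tsv"
        paths["truth"].write_text("\n".join(truth_lines) + "\n")
        return paths


def _draw_depth(rng: np.random.Generator, cfg: SimConfig) -> int:
    if cfg.depth_overdispersion is None:
        return int(round(cfg.depth_mean))
    r = cfg.depth_overdispersion
    p = r / (r + cfg.depth_mean)
    return max(int(rng.negative_binomial(r, p)), 1)


def _reads(
    rng: np.random.Generator, cfg: SimConfig, vaf: float
) -> SampleCall:
    """Draw depth and allele-split reads for a carrier at the given VAF."""
    depth = _draw_depth(rng, cfg)
    alt = int(rng.binomial(depth, vaf)) if 0.0 < vaf < 1.0 else int(round(depth * vaf))
    if vaf > 0.0 and alt == 0:
        alt = 1  # a called carrier shows at least one supporting read
    gt = (
        Genotype.HOM_ALT
        if vaf >= 0.9
        else Genotype.HET
        if vaf > 0.0
        else Genotype.HOM_REF
    )
    return SampleCall(genotype=gt, depth=depth, alt_reads=alt, ref_reads=depth - alt)


def _ref_call(rng: np.random.Generator, cfg: SimConfig, hemi: bool = False) -> SampleCall:
    depth = _draw_depth(rng, cfg)
    alt = (
        int(rng.binomial(depth, cfg.error_rate_parent_alt))
        if cfg.error_rate_parent_alt > 0
        else 0
    )
    gt = Genotype.HEMI_REF if hemi else Genotype.HOM_REF
    return SampleCall(genotype=gt, depth=depth, alt_reads=alt, ref_reads=depth - alt)


def _hemi_alt_call(rng: np.random.Generator, cfg: SimConfig) -> SampleCall:
    depth = _draw_depth(rng, cfg)
    return SampleCall(
        genotype=Genotype.HEMI_ALT, depth=depth, alt_reads=depth, ref_reads=0
    )


def _benign_scores(rng: np.random.Generator) -> dict:
    return {
        "sift": float(np.round(rng.uniform(0.2, 1.0), 3)),
        "polyphen2": float(np.round(rng.uniform(0.0, 0.3), 3)),
        "provean": float(np.round(rng.uniform(-1.5, 1.0), 2)),
    }


def _damaging_scores(rng: np.random.Generator) -> dict:
    return {
        "sift": float(np.round(rng.uniform(0.0, 0.04), 3)),
        "polyphen2": float(np.round(rng.uniform(0.9, 1.0), 3)),
        "provean": float(np.round(rng.uniform(-12.0, -3.0), 2)),
    }


def _segregating_sites(
    rng: np.random.Generator, models: Sequence[TranscriptModel], cfg: SimConfig
) -> list[tuple[VariantSite, float, str, dict]]:
    """Cohort-level segregating variants: (site, allele freq, gene, scores).

    Sites accumulate until the expected number of alt-carrying probands per
    trio reaches ``n_inherited_per_trio`` (under Hardy-Weinberg parents and
    Mendelian transmission, P(child carries) ~= 2*af*(1-af) + af^2).
    """
    autosomal = [m for m in models if m.chrom != "chrX"]
    sites: list[tuple[VariantSite, float, str, dict]] = []
    used: set[tuple] = set()
    expected_carried = 0.0
    while expected_carried < cfg.n_inherited_per_trio:
        model = autosomal[int(rng.integers(0, len(autosomal)))]
        pos = int(rng.choice(model.coding_genomic_positions()))
        site = _random_snv_at(model, pos, rng)
        if site.key in used:
            continue
        used.add(site.key)
        if rng.random() < cfg.common_af_weight:
            af = float(rng.uniform(0.005, 0.2))  # caught by the rarity filter
        else:
            af = float(rng.uniform(1e-4, 0.004))  # rare, survives it
        scores = (
            _damaging_scores(rng) if rng.random() < 0.3 else _benign_scores(rng)
        )
        sites.append((site, af, model.gene, scores))
        expected_carried += 2 * af * (1 - af) + af * af
    return sites


def _transmit(
    rng: np.random.Generator, father_alt: int, mother_alt: int
) -> tuple[int, Optional[str]]:
    """Mendelian transmission of autosomal allele counts; returns child count
    and (if exactly one parent transmitted) which parent it came from."""
    from_father = int(rng.random() < father_alt / 2)
    from_mother = int(rng.random() < mother_alt / 2)
    child = from_father + from_mother
    origin = None
    if from_father and not from_mother:
        origin = "father"
    elif from_mother and not from_father:
        origin = "mother"
    elif from_father and from_mother:
        origin = "both"
    return child, origin


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort: trio calls, annotations, callable bases, truth.

    Deterministic for a fixed config (a single seed governs everything;
    per-trio substreams are derived from it).
    """
    master = np.random.default_rng([config.seed, 104729])
    reference, models = make_toy_genome(config.seed)
    coding_by_model = {m.transcript_id: m.coding_genomic_positions() for m in models}
    ccds_length = config.ccds_length or sum(
        len(v) for k, v in coding_by_model.items()
    )
    callable_per_trio = int(round(config.callable_fraction * ccds_length))

    autosomal_models = [m for m in models if m.chrom != "chrX"]
    weights = np.array([len(coding_by_model[m.transcript_id]) for m in autosomal_models], float)
    weights /= weights.sum()

    seg_sites = _segregating_sites(master, models, config)

    classes = list(config.class_mixture.keys())
    class_p = np.array([config.class_mixture[c] for c in classes], float)

    annotations: dict[tuple, AnnotationRecord] = {}
    truth = GroundTruth()
    pedigrees: list[Pedigree] = []
    trio_calls: dict[str, list[TrioCall]] = {}
    callable_bases: dict[str, int] = {}

    def add_annotation(site: VariantSite, gene: str, af: float, scores: dict,
                       transcript_id: str = "") -> None:
        if site.key in annotations:
            return
        panel_afs = {"1000g": af, "evs": af} if af > 0 else {}
        annotations[site.key] = AnnotationRecord(
            site=site,
            gene=gene,
            transcript_id=transcript_id,
            panel_afs=panel_afs,
            inhouse_carrier_fraction=min(af, 1.0),
            **scores,
        )

    for site, af, gene, scores in seg_sites:
        add_annotation(site, gene, af, scores)

    for i in range(config.n_trios):
        rng = np.random.default_rng([config.seed, 15485863, i])
        trio_id = f"trio{i:04d}"
        sex = "M" if i % 2 == 1 else "F"
        ped = Pedigree(
            proband=f"{trio_id}-p",
            father=f"{trio_id}-f",
            mother=f"{trio_id}-m",
            proband_sex=sex,
            trio_id=trio_id,
        )
        pedigrees.append(ped)
        calls: list[TrioCall] = []
        used_sites: set[tuple] = set()
        callable_bases[trio_id] = callable_per_trio

        # -- inherited variants -------------------------------------------
        for site, af, gene, scores in seg_sites:
            father_alt = int(rng.binomial(2, af))
            mother_alt = int(rng.binomial(2, af))
            if father_alt == 0 and mother_alt == 0:
                continue
            child_alt, origin = _transmit(rng, father_alt, mother_alt)
            calls.append(
                TrioCall(
                    site=site,
                    proband=_reads(rng, config, 0.5 * child_alt),
                    father=_reads(rng, config, 0.5 * father_alt)
                    if father_alt
                    else _ref_call(rng, config),
                    mother=_reads(rng, config, 0.5 * mother_alt)
                    if mother_alt
                    else _ref_call(rng, config),
                    proband_sex=sex,
                    trio_id=trio_id,
                )
            )
            used_sites.add(site.key)
            if child_alt > 0:
                truth.inherited.append((trio_id, site, origin or "both"))

        # -- planted DNMs --------------------------------------------------
        n_dnm = int(rng.poisson(config.mu_dnm * callable_per_trio))
        for _ in range(n_dnm):
            for _attempt in range(50):
                cls = classes[int(rng.choice(len(classes), p=class_p))]
                if sex == "M" and rng.random() < 0.05:
                    hosts = [m for m in models if m.chrom == "chrX"]
                else:
                    hosts = autosomal_models
                model = hosts[int(rng.integers(0, len(hosts)))]
                try:
                    site = plant_consequence(model, cls, rng)
                except PlantingError:
                    continue
                if site.key not in used_sites:
                    break
            else:  # pragma: no cover - pathological config
                continue
            used_sites.add(site.key)
            on_male_x = sex == "M" and site.chrom == "chrX"
            if on_male_x:
                vaf = 1.0
                proband = _hemi_alt_call(rng, config)
            elif config.mosaic_fraction > 0 and rng.random() < config.mosaic_fraction:
                vaf = float(rng.uniform(0.08, 0.22))
                proband = _reads(rng, config, vaf)
            else:
                vaf = 0.5
                proband = _reads(rng, config, vaf)
            calls.append(
                TrioCall(
                    site=site,
                    proband=proband,
                    father=_ref_call(rng, config, hemi=on_male_x),
                    mother=_ref_call(rng, config),
                    proband_sex=sex,
                    trio_id=trio_id,
                )
            )
            truth.planted_dnms.append((trio_id, site, cls, vaf))
            scores = (
                _damaging_scores(rng)
                if rng.random() < config.damaging_missense_fraction
                else _benign_scores(rng)
            )
            add_annotation(site, model.gene, 0.0, scores, model.transcript_id)

        # -- artifacts ------------------------------------------------------
        if config.artifact_rate_per_type > 0:
            calls.extend(
                _make_artifacts(rng, config, models, autosomal_models, weights,
                                trio_id, sex, used_sites, truth, add_annotation)
            )
        calls.sort(key=lambda c: (c.site.chrom, c.site.pos, c.site.ref, c.site.alt))
        trio_calls[trio_id] = calls

    return SimulatedCohort(
        config=config,
        reference=reference,
        models=models,
        pedigrees=pedigrees,
        trio_calls=trio_calls,
        annotations=annotations,
        callable_bases=callable_bases,
        truth=truth,
    )


def _make_artifacts(
    rng, config, models, autosomal_models, weights, trio_id, sex, used_sites,
    truth, add_annotation,
) -> list[TrioCall]:
    """Plant the three artifact families the cascade must reject."""
    calls = []

    def fresh_snv():
        for _ in range(200):
            model = autosomal_models[int(rng.integers(0, len(autosomal_models)))]
            pos = int(rng.choice(model.coding_genomic_positions()))
            site = _random_snv_at(model, pos, rng)
            if site.key not in used_sites:
                used_sites.add(site.key)
                return site, model
        raise RuntimeError("toy genome exhausted")

    # (a) parent shows alt reads: not truly de novo
    for _ in range(int(rng.poisson(config.artifact_rate_per_type))):
        site, model = fresh_snv()
        depth = _draw_depth(rng, config)
        parent_alt = max(2, int(round(depth * float(rng.uniform(0.05, 0.3)))))
        dirty = SampleCall(
            genotype=Genotype.HOM_REF,
            depth=depth,
            alt_reads=parent_alt,
            ref_reads=depth - parent_alt,
        )
        father_dirty = rng.random() < 0.5
        calls.append(
            TrioCall(
                site=site,
                proband=_reads(rng, config, 0.5),
                father=dirty if father_dirty else _ref_call(rng, config),
                mother=_ref_call(rng, config) if father_dirty else dirty,
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
        truth.artifacts.append((trio_id, site, "parental_alt_reads"))
        add_annotation(site, model.gene, 0.0, _benign_scores(rng))

    # (b) weak proband support: < 4 alt reads or < 20% VAF
    for _ in range(int(rng.poisson(config.artifact_rate_per_type))):
        site, model = fresh_snv()
        depth = max(_draw_depth(rng, config), 25)
        if rng.random() < 0.5:
            alt = int(rng.integers(1, 4))  # too few alt reads
        else:
            alt = max(4, int(round(depth * float(rng.uniform(0.02, 0.15)))))
            alt = min(alt, max(1, int(depth * 0.19)))  # VAF below 20%
        weak = SampleCall(
            genotype=Genotype.HET, depth=depth, alt_reads=alt, ref_reads=depth - alt
        )
        calls.append(
            TrioCall(
                site=site,
                proband=weak,
                father=_ref_call(rng, config),
                mother=_ref_call(rng, config),
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
        truth.artifacts.append((trio_id, site, "weak_proband_support"))
        add_annotation(site, model.gene, 0.0, _benign_scores(rng))

    # (c) common variant mis-called as a Mendelian violation
    for _ in range(int(rng.poisson(config.artifact_rate_per_type))):
        site, model = fresh_snv()
        calls.append(
            TrioCall(
                site=site,
                proband=_reads(rng, config, 0.5),
                father=_ref_call(rng, config),
                mother=_ref_call(rng, config),
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
        truth.artifacts.append((trio_id, site, "common_variant"))
        add_annotation(
            site, model.gene, float(rng.uniform(0.01, 0.2)), _benign_scores(rng)
        )
    return calls


# --------------------------------------------------------------------------
# planted recessive / X-linked cases for the inherited screen
# --------------------------------------------------------------------------


def make_inherited_case(
    models: Sequence[TranscriptModel],
    mechanism: str,
    rng: np.random.Generator,
    cfg: Optional[SimConfig] = None,
    trio_id: str = "case",
) -> tuple[Pedigree, list[TrioCall], dict[tuple, AnnotationRecord]]:
    """Build one trio carrying a planted recessive/X-linked candidate genotype.

    ``mechanism`` is ``hemizygous_x`` (male proband, carrier mother),
    ``homozygous`` (both parents het) or ``compound_het`` (two hets in one
    gene, one per parent).  Variants are rare, damaging missense.
    """
    cfg = cfg or SimConfig.noise_free()
    sex = "M" if mechanism == "hemizygous_x" else "F"
    ped = Pedigree(
        proband=f"{trio_id}-p", father=f"{trio_id}-f", mother=f"{trio_id}-m",
        proband_sex=sex, trio_id=trio_id,
    )
    anns: dict[tuple, AnnotationRecord] = {}
    calls: list[TrioCall] = []

    def missense_on(model) -> VariantSite:
        site = plant_consequence(model, ConsequenceClass.MISSENSE, rng)
        anns[site.key] = AnnotationRecord(
            site=site, gene=model.gene, transcript_id=model.transcript_id,
            panel_afs={"1000g": 0.0005}, inhouse_carrier_fraction=0.001,
            **_damaging_scores(rng),
        )
        return site

    if mechanism == "hemizygous_x":
        model = next(m for m in models if m.chrom == "chrX")
        site = missense_on(model)
        calls.append(
            TrioCall(
                site=site,
                proband=_hemi_alt_call(rng, cfg),
                father=_ref_call(rng, cfg, hemi=True),
                mother=_reads(rng, cfg, 0.5),
                proband_sex="M",
                trio_id=trio_id,
            )
        )
    elif mechanism == "homozygous":
        model = next(m for m in models if m.chrom != "chrX")
        site = missense_on(model)
        calls.append(
            TrioCall(
                site=site,
                proband=_reads(rng, cfg, 1.0),
                father=_reads(rng, cfg, 0.5),
                mother=_reads(rng, cfg, 0.5),
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
    elif mechanism == "compound_het":
        model = next(m for m in models if m.chrom != "chrX")
        site1 = missense_on(model)
        site2 = missense_on(model)
        while site2.key == site1.key:
            site2 = missense_on(model)
        calls.append(
            TrioCall(
                site=site1,
                proband=_reads(rng, cfg, 0.5),
                father=_reads(rng, cfg, 0.5),
                mother=_ref_call(rng, cfg),
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
        calls.append(
            TrioCall(
                site=site2,
                proband=_reads(rng, cfg, 0.5),
                father=_ref_call(rng, cfg),
                mother=_reads(rng, cfg, 0.5),
                proband_sex=sex,
                trio_id=trio_id,
            )
        )
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return ped, calls, anns
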