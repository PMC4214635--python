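"""Readers and writers for the formats the pipeline touches.

Trio calls come in as multi-sample VCF (parsed with pysam), transcript
models as GFF3 plus a FASTA reference, annotations and DNM tables as
tab-delimited files (pandas), and gene panels as one-symbol-per-line text.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .consequence import ConsequenceClass
from .filters import DNMRecord
from .transcripts import TranscriptModel
from .types import (
    AnnotationRecord,
    GenePanel,
    Genotype,
    GeneTier,
    SampleCall,
    TrioCall,
    VariantSite,
    is_x_chromosome,
)


class VCFParseError(ValueError):
    pass


@dataclass(frozen=True)
class Pedigree:
    """Sample-ID-to-role map for one trio."""

    proband: str
    father: str
    mother: str
    proband_sex: str = "F"
    trio_id: str = "trio"

    @classmethod
    def from_ped_file(cls, path: str | Path) -> "Pedigree":
        """Parse a 6-column PED file describing a single trio.

        Columns: family, individual, father, mother, sex (1=M, 2=F),
        phenotype (2=affected).  The affected child with both parents named
        is the proband.
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
        for fam, ind, fa, mo, sex, *_ in rows:
            if fa != "0" and mo != "0":
                return cls(
                    proband=ind,
                    father=fa,
                    mother=mo,
                    proband_sex="M" if sex == "1" else "F",
                    trio_id=fam,
                )
        raise ValueError(f"{path}: no individual with two named parents")


# --------------------------------------------------------------------------
# trio VCF
# --------------------------------------------------------------------------


def _genotype_for_allele(
    gt: tuple, allele_index: int, chrom: str, sex: str
) -> Genotype:
    if gt is None or any(a is None for a in gt):
        return Genotype.MISSING
    count = sum(1 for a in gt if a == allele_index)
    hemi = len(gt) == 1 or (sex == "M" and is_x_chromosome(chrom))
    if count == 0:
        return Genotype.HEMI_REF if hemi else Genotype.HOM_REF
    if count == len(gt):
        return Genotype.HEMI_ALT if hemi else Genotype.HOM_ALT
    return Genotype.HET


def _sample_call(
    sample, allele_index: int, chrom: str, sex: str
) -> SampleCall:
    gt = sample.get("GT")
    ad = sample.get("AD")
    depth = sample.get("DP")
    if ad is not None and any(a is None for a in ad):
        ad = None
    alt_reads = int(ad[allele_index]) if ad is not None else 0
    ref_reads = int(ad[0]) if ad is not None else 0
    if depth is None:
        # missing DP with present AD: reconstitute as the AD sum
        depth = int(sum(ad)) if ad is not None else 0
    depth = max(int(depth), alt_reads + ref_reads)
    return SampleCall(
        genotype=_genotype_for_allele(gt, allele_index, chrom, sex),
        depth=depth,
        alt_reads=alt_reads,
        ref_reads=ref_reads,
    )


def read_trio_vcf(
    path: str | Path, pedigree: Pedigree
) -> list[TrioCall]:
    """Read a multi-sample VCF into TrioCalls, decomposing multi-allelics.

    One TrioCall is produced per (record, alt allele); records with a
    missing genotype in any member are retained with that member's genotype
    set to ``missing``.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for role, sid in (
            ("proband", pedigree.proband),
            ("father", pedigree.father),
            ("mother", pedigree.mother),
        ):
            if sid not in samples:
                raise VCFParseError(f"{path}: {role} sample {sid!r} not in header")
        out: list[TrioCall] = []
        for line_no, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts, start=1):
                    if alt is None or set(alt) - set("ACGT"):
                        continue  # symbolic or spanning-deletion alleles
                    site = VariantSite(rec.chrom, rec.pos, rec.ref, alt)
                    calls = {}
                    for role, sid in (
                        ("proband", pedigree.proband),
                        ("father", pedigree.father),
                        ("mother", pedigree.mother),
                    ):
                        sex = pedigree.proband_sex if role == "proband" else (
                            "M" if role == "father" else "F"
                        )
                        calls[role] = _sample_call(rec.samples[sid], ai, rec.chrom, sex)
                    out.append(
                        TrioCall(
                            site=site,
                            proband=calls["proband"],
                            father=calls["father"],
                            mother=calls["mother"],
                            proband_sex=pedigree.proband_sex,
                            trio_id=pedigree.trio_id,
                        )
                    )
            except (ValueError, KeyError) as exc:
                raise VCFParseError(f"{path}: malformed record #{line_no}: {exc}") from exc
    return out


def write_trio_vcf(
    path: str | Path,
    trios: Sequence[TrioCall],
    pedigree: Pedigree,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write TrioCalls of one trio as a minimal VCF 4.2 file."""
    gt_map = {
        Genotype.HOM_REF: "0/0",
        Genotype.HET: "0/1",
        Genotype.HOM_ALT: "1/1",
        Genotype.HEMI_REF: "0",
        Genotype.HEMI_ALT: "1",
        Genotype.MISSING: "./.",
    }
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contig_lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join([pedigree.proband, pedigree.father, pedigree.mother]),
    ]
    for t in sorted(trios, key=lambda t: (t.site.chrom, t.site.pos, t.site.ref, t.site.alt)):
        cols = [
            t.site.chrom,
            str(t.site.pos),
            ".",
            t.site.ref,
            t.site.alt,
            ".",
            "PASS",
            ".",
            "GT:DP:AD",
        ]
        for call in (t.proband, t.father, t.mother):
            cols.append(
                f"{gt_map[call.genotype]}:{call.depth}:{call.ref_reads},{call.alt_reads}"
            )
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# transcript models (GFF3 + FASTA)
# --------------------------------------------------------------------------


def read_transcript_models(path: str | Path, fasta: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GFF3 file plus a FASTA reference.

    Expects ``mRNA`` features with ``ID`` and ``gene`` attributes and child
    ``exon``/``CDS`` features referring to them via ``Parent``.  A CDS whose
    total length is not divisible by 3 is a fatal error naming the
    transcript.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ref = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_parts = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds_parts:
            raise ValueError(f"transcript {mrna.id}: missing exon or CDS features")
        gene = mrna.attributes.get("gene", [mrna.id])[0]
        models.append(
            TranscriptModel(
                gene=gene,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_start=cds_parts[0][0],
                cds_end=cds_parts[-1][1],
                contig_seq=str(ref[mrna.seqid][:]),
            )
        )
    return models


def write_transcript_gff3(path: str | Path, models: Sequence[TranscriptModel]) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        span = (m.exons[0][0], m.exons[-1][1])
        lines.append(
            f"{m.chrom}\ttriodnm\tmRNA\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};gene={m.gene}"
        )
        for s, e in m.exons:
            lines.append(
                f"{m.chrom}\ttriodnm\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"Parent={m.transcript_id}"
            )
        for s, e in m.coding_intervals:
            lines.append(
                f"{m.chrom}\ttriodnm\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"Parent={m.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(path: str | Path, contigs: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# annotation table
# --------------------------------------------------------------------------

_ANN_FIXED = [
    "chrom", "pos", "ref", "alt", "gene", "transcript_id",
    "sift", "polyphen2", "provean", "inhouse_carrier_fraction",
    "splice_prediction_flag",
]


def write_annotation_table(
    path: str | Path, annotations: Iterable[AnnotationRecord]
) -> None:
    rows = []
    for ann in annotations:
        row = {
            "chrom": ann.site.chrom,
            "pos": ann.site.pos,
            "ref": ann.site.ref,
            "alt": ann.site.alt,
            "gene": ann.gene,
            "transcript_id": ann.transcript_id,
            "sift": ann.sift,
            "polyphen2": ann.polyphen2,
            "provean": ann.provean,
            "inhouse_carrier_fraction": ann.inhouse_carrier_fraction,
            "splice_prediction_flag": int(ann.splice_prediction_flag),
        }
        for panel, af in ann.panel_afs.items():
            row[f"af_{panel}"] = af
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=_ANN_FIXED)
    fixed = [c for c in _ANN_FIXED if c in df.columns]
    extra = sorted(c for c in df.columns if c not in _ANN_FIXED)
    df[fixed + extra].to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> dict[tuple, AnnotationRecord]:
    """Read the tab-delimited annotation table keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[tuple, AnnotationRecord] = {}
    af_cols = [c for c in df.columns if c.startswith("af_")]
    for row in df.itertuples(index=False):
        d = row._asdict()
        site = VariantSite(d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        panel_afs = {
            c[3:]: float(d[c]) for c in af_cols if not _isna(d[c])
        }
        ann = AnnotationRecord(
            site=site,
            gene=str(d["gene"]),
            transcript_id=str(d.get("transcript_id", "")),
            sift=None if _isna(d.get("sift")) else float(d["sift"]),
            polyphen2=None if _isna(d.get("polyphen2")) else float(d["polyphen2"]),
            provean=None if _isna(d.get("provean")) else float(d["provean"]),
            panel_afs=panel_afs,
            inhouse_carrier_fraction=float(d.get("inhouse_carrier_fraction", 0.0) or 0.0),
            splice_prediction_flag=bool(int(d.get("splice_prediction_flag", 0) or 0)),
        )
        out[site.key] = ann
    return out


def _isna(v) -> bool:
    if v is None:
        return True
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


# --------------------------------------------------------------------------
# DNM table
# --------------------------------------------------------------------------

_DNM_COLUMNS = [
    "trio_id", "gene", "gene_tier", "chrom", "pos", "ref", "alt",
    "consequence", "mosaic_flag", "predicted_damaging", "unannotated",
    "genotype", "depth", "alt_reads", "ref_reads",
]


def write_dnm_table(records: Sequence[DNMRecord], path: str | Path) -> None:
    """Write DNM records as a round-trippable tab-delimited table."""
    rows = []
    for r in records:
        rows.append(
            {
                "trio_id": r.trio_id,
                "gene": r.gene,
                "gene_tier": r.gene_tier.value,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref,
                "alt": r.site.alt,
                "consequence": "" if r.consequence is None else r.consequence.value,
                "mosaic_flag": int(r.mosaic_flag),
                "predicted_damaging": int(r.predicted_damaging),
                "unannotated": int(r.unannotated),
                "genotype": r.proband_call.genotype.value,
                "depth": r.proband_call.depth,
                "alt_reads": r.proband_call.alt_reads,
                "ref_reads": r.proband_call.ref_reads,
            }
        )
    df = pd.DataFrame(rows, columns=_DNM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_dnm_table(path: str | Path) -> list[DNMRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "consequence": str})
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cons = d.get("consequence")
        out.append(
            DNMRecord(
                trio_id=str(d["trio_id"]),
                site=VariantSite(d["chrom"], int(d["pos"]), d["ref"], d["alt"]),
                proband_call=SampleCall(
                    genotype=Genotype(d["genotype"]),
                    depth=int(d["depth"]),
                    alt_reads=int(d["alt_reads"]),
                    ref_reads=int(d["ref_reads"]),
                ),
                consequence=None
                if cons is None or _isna(cons) or cons == ""
                else ConsequenceClass(cons),
                mosaic_flag=bool(int(d["mosaic_flag"])),
                predicted_damaging=bool(int(d["predicted_damaging"])),
                gene=str(d["gene"]),
                gene_tier=GeneTier(d["gene_tier"]),
                unannotated=bool(int(d["unannotated"])),
            )
        )
    return out


# --------------------------------------------------------------------------
# gene panels & callable summaries
# --------------------------------------------------------------------------


def read_gene_panel(path: str | Path, name: str, tier: GeneTier) -> GenePanel:
    """Read a one-gene-per-line panel file ('#' comments allowed)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        g = line.strip()
        if g and not g.startswith("#"):
            genes.append(g)
    if len(genes) != len(set(genes)):
        raise ValueError(f"{path}: duplicate gene symbols in panel")
    return GenePanel(name=name, genes=frozenset(genes), tier=tier)


def write_callable_summary(path: str | Path, per_trio: Mapping[str, int]) -> None:
    df = pd.DataFrame(
        {"trio_id": list(per_trio), "callable_bases": list(per_trio.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_callable_summary(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"trio_id": str})
    return dict(zip(df["trio_id"], df["callable_bases"].astype(int)))
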