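"""Consequence classification against hand-built transcripts and a
rebuild-the-CDS translation oracle."""
import numpy as np
import pytest
from Bio.Seq import Seq

from triodnm.consequence import (
    ConsequenceClass as C,
    DamagingCriteria,
    GENETIC_CODE,
    assign_gene_tier,
    classify,
    is_lof_snv,
    is_predicted_damaging,
    translate,
)
from triodnm.datasets import load_default_panels
from triodnm.transcripts import reverse_complement
from triodnm.types import AnnotationRecord, GeneTier, VariantSite

from conftest import make_transcript


@pytest.fixture(scope="module")
def two_exon():
    """+-strand 2-exon gene: exons 11-19 and 40-48, CDS = 18 bp.

    Exon 1 sequence ATGGCTTGG (M A W), exon 2 GCCTACTAA (A Y *).
    Intron spans 20-39.
    """
    intron = "GT" + "A" * 16 + "AG"  # 20 bases: 20-39
    seq = "AAAAAAAAAA" + "ATGGCTTGG" + intron + "GCCTACTAA" + "AAAAAAAAAA"
    return make_transcript(seq, [(11, 19), (40, 48)])


def test_two_exon_structure(two_exon):
    assert two_exon.cds_length == 18
    assert two_exon.cds_sequence() == "ATGGCTTGGGCCTACTAA"
    assert translate(two_exon.cds_sequence()) == "MAWAY*"


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (19, "G", "A", C.NONSENSE),          # TGG (17-19) -> TGA (stop)
        (13, "G", "T", C.MISSENSE),          # ATG -> ATT  M->I
        (16, "T", "C", C.SYNONYMOUS),        # GCT (14-16) -> GCC keeps Ala
        (42, "C", "T", C.SPLICE_REGION_SYNONYMOUS),  # GCC (40-42) -> GCT, Ala,
                                             # within 3 bases of the exon start
        (21, "T", "C", C.CANONICAL_SPLICE),  # donor +2
        (20, "G", "A", C.CANONICAL_SPLICE),  # donor +1
        (38, "A", "C", C.CANONICAL_SPLICE),  # acceptor -2
        (39, "G", "C", C.CANONICAL_SPLICE),  # acceptor -1
        (22, "A", "C", C.CONSENSUS_SPLICE),  # donor +3
        (25, "A", "C", C.CONSENSUS_SPLICE),  # donor +6
        (37, "A", "C", C.CONSENSUS_SPLICE),  # acceptor -3
        (26, "A", "C", C.NONCODING),         # donor +7: deep intron
        (5, "A", "C", C.NONCODING),          # upstream of the gene
    ],
)
def test_snv_positions(two_exon, pos, ref, alt, expected):
    site = VariantSite("chrT", pos, ref, alt)
    if expected is not C.NONCODING:
        # sanity: the stated ref matches the contig except where irrelevant
        assert two_exon.fetch(pos, pos) == ref or pos > 19
    assert classify(site, two_exon) is expected


def test_synonymous_away_from_boundary(two_exon):
    # exon2 TAC -> TAT keeps Tyr; position 45 is 4 bases from both boundaries
    assert two_exon.fetch(45, 45) == "C"
    assert classify(VariantSite("chrT", 45, "C", "T"), two_exon) is C.SYNONYMOUS


def test_coding_indels(two_exon):
    # 2-base deletion inside exon 2 -> frameshift
    ref = two_exon.fetch(41, 43)
    assert (
        classify(VariantSite("chrT", 41, ref, ref[0]), two_exon)
        is C.FRAMESHIFT_DELETION
    )
    # 3-base deletion -> in-frame
    ref = two_exon.fetch(41, 44)
    assert (
        classify(VariantSite("chrT", 41, ref, ref[0]), two_exon)
        is C.INFRAME_DELETION
    )
    # insertions
    base = two_exon.fetch(42, 42)
    assert (
        classify(VariantSite("chrT", 42, base, base + "T"), two_exon)
        is C.FRAMESHIFT_INSERTION
    )
    assert (
        classify(VariantSite("chrT", 42, base, base + "TTT"), two_exon)
        is C.INFRAME_INSERTION
    )


def test_minus_strand_mirror(two_exon):
    """Reverse-complementing the contig and flipping strand preserves classes."""
    L = len(two_exon.contig_seq)
    mirrored = make_transcript(
        reverse_complement(two_exon.contig_seq),
        [(L - e + 1, L - s + 1) for s, e in reversed(two_exon.exons)],
        strand="-",
    )
    rng = np.random.default_rng(77)
    for _ in range(300):
        pos = int(rng.integers(1, L + 1))
        ref = two_exon.fetch(pos, pos)
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        fwd = classify(VariantSite("chrT", pos, ref, alt), two_exon)
        mpos = L - pos + 1
        rev = classify(
            VariantSite(
                "chrT", mpos, reverse_complement(ref), reverse_complement(alt)
            ),
            mirrored,
        )
        assert fwd is rev, (pos, ref, alt, fwd, rev)


def _oracle_snv_class(site, model):
    """Independent oracle: rebuild the mutant CDS, translate with biopython."""
    seq = list(model.contig_seq)
    seq[site.pos - 1] = site.alt
    mutant = model.__class__(
        gene=model.gene,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=model.exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
        contig_seq="".join(seq),
    )
    old = str(Seq(model.cds_sequence()).translate())
    new = str(Seq(mutant.cds_sequence()).translate())
    assert len(old) == len(new)
    idx = model.cds_index(site.pos) // 3
    if new[idx] == "*" and old[idx] != "*":
        return C.NONSENSE
    if new[idx] == old[idx]:
        return "synonymous"
    return C.MISSENSE


def test_classifier_agrees_with_translation_oracle(toy_models, rng):
    """Random coding SNVs on random toy transcripts match the oracle that
    rebuilds and translates the whole mutant CDS."""
    checked = 0
    while checked < 400:
        model = toy_models[int(rng.integers(0, len(toy_models)))]
        coding = model.coding_genomic_positions()
        pos = int(rng.choice(coding))
        ref = model.fetch(pos, pos)
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        site = VariantSite(model.chrom, pos, ref, alt)
        got = classify(site, model)
        want = _oracle_snv_class(site, model)
        if want == "synonymous":
            assert got in (C.SYNONYMOUS, C.SPLICE_REGION_SYNONYMOUS)
        else:
            assert got is want, (site, got, want)
        checked += 1


def test_genetic_code_matches_biopython():
    for codon, aa in GENETIC_CODE.items():
        assert str(Seq(codon).translate()) == aa


def test_lof_snv_membership():
    assert is_lof_snv(C.NONSENSE)
    assert is_lof_snv(C.CANONICAL_SPLICE)
    assert not is_lof_snv(C.FRAMESHIFT_DELETION)  # LoF but not an SNV class
    assert not is_lof_snv(C.CONSENSUS_SPLICE)
    assert not is_lof_snv(C.MISSENSE)


def _ann(**kw):
    site = VariantSite("chr1", 100, "A", "G")
    return AnnotationRecord(site=site, gene="G1", **kw)


def test_damaging_prediction_rules():
    crit = DamagingCriteria()
    # unanimous damaging scores (the published convention for reported hits)
    assert is_predicted_damaging(
        _ann(sift=0.0, polyphen2=1.0, provean=-11.5), C.MISSENSE, crit
    )
    # one benign predictor vetoes
    assert not is_predicted_damaging(
        _ann(sift=0.30, polyphen2=1.0, provean=-11.5), C.MISSENSE, crit
    )
    # unscored missense is not called damaging
    assert not is_predicted_damaging(_ann(), C.MISSENSE, crit)
    # truncating classes need no scores
    assert is_predicted_damaging(None, C.NONSENSE, crit)
    assert is_predicted_damaging(None, C.FRAMESHIFT_INSERTION, crit)
    # in-frame indels judged by PROVEAN alone
    assert is_predicted_damaging(_ann(provean=-12.3), C.INFRAME_DELETION, crit)
    assert not is_predicted_damaging(_ann(provean=-1.0), C.INFRAME_DELETION, crit)
    # synonymous needs the external splice-prediction flag and splice region
    assert not is_predicted_damaging(_ann(), C.SYNONYMOUS, crit)
    assert is_predicted_damaging(
        _ann(splice_prediction_flag=True), C.SPLICE_REGION_SYNONYMOUS, crit
    )
    assert not is_predicted_damaging(_ann(), C.SPLICE_REGION_SYNONYMOUS, crit)


def test_gene_tiers_from_packaged_panels():
    panels = load_default_panels()
    assert assign_gene_tier("ARID1B", panels) is GeneTier.KNOWN_ID
    assert assign_gene_tier("HNRNPU", panels) is GeneTier.CANDIDATE_ID
    assert assign_gene_tier("NOVELGENE1", panels) is GeneTier.UNKNOWN


def test_invalid_transcripts_rejected():
    seq = "A" * 100
    with pytest.raises(ValueError, match="not divisible"):
        make_transcript(seq, [(10, 17)])  # 8 bp CDS
    with pytest.raises(ValueError, match="overlapping"):
        make_transcript(seq, [(10, 21), (20, 31)])
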