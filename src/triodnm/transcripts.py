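"""Transcript models: exon/CDS structure plus sequence access.

Intervals are 1-based, fully closed, stored in genomic order regardless of
strand; transcription order is derived from ``strand`` where needed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript on one contig.

    Parameters
    ----------
    gene, transcript_id : str
        Symbols used in reports and annotation joins.
    chrom : str
        Contig name.
    strand : str
        ``+`` or ``-``.
    exons : sequence of (start, end)
        1-based closed exon intervals, sorted, non-overlapping.
    cds_start, cds_end : int
        Genomic bounds of the coding region (inclusive), inside the exon span.
    contig_seq : str
        Full sequence of the contig (uppercase A/C/G/T).
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    contig_seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon {start}-{end} reversed")
            if start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping at {start}"
                )
            prev_end = end
        span_start, span_end = self.exons[0][0], self.exons[-1][1]
        if not (span_start <= self.cds_start <= self.cds_end <= span_end):
            raise ValueError(f"{self.transcript_id}: CDS bounds outside exon span")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    # ---- sequence access -------------------------------------------------

    def fetch(self, start: int, end: int) -> str:
        """Contig sequence for the closed interval [start, end], forward strand."""
        if start < 1 or end > len(self.contig_seq):
            raise ValueError(f"interval {start}-{end} outside contig")
        return self.contig_seq[start - 1 : end].upper()

    # ---- structure -------------------------------------------------------

    @property
    def coding_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals clipped to the CDS, genomic order."""
        out = []
        for start, end in self.exons:
            s, e = max(start, self.cds_start), min(end, self.cds_end)
            if s <= e:
                out.append((s, e))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.coding_intervals)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Closed intervals between consecutive exons, genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    def contains(self, pos: int) -> bool:
        return self.exons[0][0] <= pos <= self.exons[-1][1]

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.coding_intervals)

    def is_intronic(self, pos: int) -> bool:
        return self.contains(pos) and not self.in_exon(pos)

    def cds_index(self, pos: int) -> int:
        """0-based index of a genomic position within the CDS, transcription order."""
        offset = 0
        for s, e in self.coding_intervals:
            if s <= pos <= e:
                offset += pos - s
                break
            offset += e - s + 1
        else:
            raise ValueError(f"position {pos} not in CDS of {self.transcript_id}")
        if self.strand == "-":
            return self.cds_length - 1 - offset
        return offset

    def coding_genomic_positions(self) -> list[int]:
        return [p for s, e in self.coding_intervals for p in range(s, e + 1)]

    def cds_sequence(self) -> str:
        """Coding sequence in transcription order (reverse-complemented on '-')."""
        seq = "".join(self.fetch(s, e) for s, e in self.coding_intervals)
        return reverse_complement(seq) if self.strand == "-" else seq

    # ---- splice windows --------------------------------------------------

    def canonical_splice_positions(self) -> frozenset[int]:
        """The two intronic bases flanking every internal exon boundary.

        These hold the near-invariant GT (donor) and AG (acceptor)
        dinucleotides; which side is donor vs acceptor depends on strand, but
        the canonical window is the same set of positions either way.
        """
        out: set[int] = set()
        for istart, iend in self.introns:
            out.update(range(istart, min(istart + 2, iend + 1)))
            out.update(range(max(iend - 1, istart), iend + 1))
        return frozenset(out)

    def consensus_splice_positions(self) -> frozenset[int]:
        """Wider intronic window: donor +1..+6 and acceptor -3..-1, strand-aware.

        Includes the canonical positions (canonical is a strict subset
        whenever an intron is long enough to host the wider window).
        """
        out: set[int] = set(self.canonical_splice_positions())
        for istart, iend in self.introns:
            if self.strand == "+":
                donor_extra = range(istart + 2, min(istart + 6, iend + 1))
                acceptor_extra = range(max(iend - 2, istart), iend - 1)
            else:
                donor_extra = range(max(iend - 5, istart), iend - 1)
                acceptor_extra = range(istart + 2, min(istart + 3, iend + 1))
            out.update(donor_extra)
            out.update(acceptor_extra)
        return frozenset(out)

    def splice_region_exonic_positions(self) -> frozenset[int]:
        """The 3 exonic bases on each side of every internal exon boundary."""
        out: set[int] = set()
        n = len(self.exons)
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # exon start follows an intron
                out.update(range(s, min(s + 3, e + 1)))
            if i < n - 1:  # exon end precedes an intron
                out.update(range(max(e - 2, s), e + 1))
        return frozenset(out)
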