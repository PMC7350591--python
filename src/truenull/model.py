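"""Domain model for genes, transcripts and contig sequences.

Internal coordinates are 0-based half-open throughout; conversion to the
1-based inclusive GTF convention happens only in :mod:`truenull.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")


class ValidationError(ValueError):
    """An annotation object violates a structural invariant."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.name!r} is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"contig {self.name!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonInterval:
    """Genomic exon span: 0-based start (inclusive), end (exclusive)."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad exon interval [{self.start}, {self.end}) on {self.contig}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One isoform: an ordered exon chain plus optional CDS bounds.

    ``flag_cds_start_nf`` / ``flag_cds_end_nf`` mirror the Ensembl
    ``cds_start_NF`` / ``cds_end_NF`` tags: the CDS is annotated but its
    start (resp. stop) codon is not asserted, i.e. the coding sequence is
    5'- (resp. 3'-) incomplete.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: List[ExonInterval]
    cds_start_genomic: Optional[int] = None
    cds_end_genomic: Optional[int] = None
    flag_cds_start_nf: bool = False
    flag_cds_end_nf: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        strands = {e.strand for e in self.exons}
        contigs = {e.contig for e in self.exons}
        if len(strands) != 1 or len(contigs) != 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes strands or contigs"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"transcript {self.transcript_id} exons overlap or are unsorted"
                )
        for pos in (self.cds_start_genomic, self.cds_end_genomic):
            if pos is not None and not self._covers(pos):
                raise ValidationError(
                    f"transcript {self.transcript_id} CDS bound {pos} outside exons"
                )

    def _covers(self, pos: int) -> bool:
        # allow the exclusive CDS end to sit on an exon end boundary
        return any(e.start <= pos <= e.end for e in self.exons)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_genomic is not None or self.flag_cds_start_nf

    def junction_offsets(self) -> List[int]:
        """Transcript-space offsets of exon-exon junctions (first base of
        each downstream exon, in 5'->3' order)."""
        lengths = [e.length for e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        offsets, cum = [], 0
        for ln in lengths[:-1]:
            cum += ln
            offsets.append(cum)
        return offsets


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    strand: str
    transcripts: List[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.strand != self.strand:
                raise ValidationError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on id or strand"
                )

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def exon_union(self) -> List[ExonInterval]:
        """Distinct exon intervals across all isoforms, genomic order."""
        seen = {}
        for t in self.transcripts:
            for e in t.exons:
                seen[(e.start, e.end)] = e
        return [seen[k] for k in sorted(seen)]

    @property
    def span(self) -> tuple:
        exons = self.exon_union()
        return exons[0].start, exons[-1].end


@dataclass
class Annotation:
    """A contig collection plus a gene collection (sequences optional)."""

    contigs: Dict[str, Contig] = field(default_factory=dict)
    genes: Dict[str, GeneModel] = field(default_factory=dict)
    provenance: str = ""

    def validate(self) -> None:
        """Check exon/contig consistency once sequences are attached."""
        for gene in self.genes.values():
            for t in gene.transcripts:
                for e in t.exons:
                    if self.contigs:
                        if e.contig not in self.contigs:
                            raise ValidationError(
                                f"exon contig {e.contig!r} missing from contigs"
                            )
                        if e.end > len(self.contigs[e.contig]):
                            raise ValidationError(
                                f"exon [{e.start},{e.end}) outside contig "
                                f"{e.contig!r} (len {len(self.contigs[e.contig])})"
                            )

    def gene_by_symbol(self, symbol: str) -> GeneModel:
        for g in self.genes.values():
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)


def splice_mrna(transcript: TranscriptModel, contigs: Dict[str, Contig]) -> str:
    """Concatenate exon sequences 5'->3'; minus-strand transcripts are
    reverse-complemented. Length always equals the sum of exon lengths."""
    if transcript.contig not in contigs:
        raise KeyError(f"contig {transcript.contig!r} not loaded")
    seq = contigs[transcript.contig].sequence
    parts = [seq[e.start : e.end] for e in transcript.exons]
    mrna = "".join(parts)
    if transcript.strand == "-":
        mrna = reverse_complement(mrna)
    return mrna


def transcript_coord(transcript: TranscriptModel, genomic_pos: int) -> Optional[int]:
    """Map a genomic position to its transcript-space offset.

    Returns None for intronic / out-of-transcript positions.
    """
    exons = transcript.exons
    if transcript.strand == "+":
        cum = 0
        for e in exons:
            if e.start <= genomic_pos < e.end:
                return cum + (genomic_pos - e.start)
            cum += e.length
    else:
        cum = 0
        for e in reversed(exons):
            if e.start <= genomic_pos < e.end:
                return cum + (e.end - 1 - genomic_pos)
            cum += e.length
    return None


def genomic_coord(transcript: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`transcript_coord`; raises IndexError if out of range."""
    if offset < 0:
        raise IndexError(offset)
    exons = transcript.exons if transcript.strand == "+" else list(reversed(transcript.exons))
    cum = 0
    for e in exons:
        if offset < cum + e.length:
            within = offset - cum
            return e.start + within if transcript.strand == "+" else e.end - 1 - within
        cum += e.length
    raise IndexError(f"offset {offset} beyond spliced length {cum}")
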