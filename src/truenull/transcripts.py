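"""Enumerate candidate mutant mRNAs from an edited locus.

Enumeration is rule-based and exhaustive within four event classes --
deletion-joined splicing, En2 splice-acceptor retention, cassette-pA
truncation, and alternative-first-exon usage -- with no splice-strength
model: the outputs are candidates for ORF/NMD triage, not likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .alleles import MutantLocus
from .model import reverse_complement

EXON_SKIP_JOIN = "EXON_SKIP_JOIN"
SA_RETAINED = "SA_RETAINED"
PA_TRUNCATED = "PA_TRUNCATED"
ALT_FIRST_EXON = "ALT_FIRST_EXON"
NF_UNTOUCHED = "NF_UNTOUCHED"

_EVENT_RANK = {
    EXON_SKIP_JOIN: 0,
    SA_RETAINED: 1,
    PA_TRUNCATED: 2,
    ALT_FIRST_EXON: 3,
    NF_UNTOUCHED: 4,
}


@dataclass
class SplicingRuleSet:
    """Which splicing outcomes the enumerator is allowed to propose."""

    allow_exon_skip_join: bool = True
    allow_sa_retention: bool = True
    allow_pa_truncation: bool = True
    allow_alt_first_exon: bool = True
    alt_first_exon_offset: int = 199
    alt_first_exon_length: int = 100
    max_variants: int = 50

    def __post_init__(self) -> None:
        if self.alt_first_exon_offset <= 0 or self.alt_first_exon_length <= 0:
            raise ValueError("alternative-first-exon offsets must be positive")
        if self.max_variants < 1:
            raise ValueError("max_variants must be at least 1")


@dataclass(frozen=True)
class Segment:
    """One spliced block of a mutant transcript (edited-contig coordinates)."""

    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MutantTranscript:
    source_isoform: str
    chain: List[Segment]  # genomic order on the edited contig
    strand: str
    mrna: str
    events: List[str]

    @property
    def variant_id(self) -> str:
        return f"{self.source_isoform}|{'+'.join(self.events)}"

    def _ordered(self) -> List[Segment]:
        return self.chain if self.strand == "+" else list(reversed(self.chain))

    def junctions(self) -> List[int]:
        """Transcript-space offsets of splice junctions (first base of each
        downstream segment)."""
        offsets, cum = [], 0
        for seg in self._ordered()[:-1]:
            cum += seg.length
            offsets.append(cum)
        return offsets

    def segment_span(self, label: str) -> Optional[Tuple[int, int]]:
        """Transcript-space [start, end) of the first segment with ``label``."""
        cum = 0
        for seg in self._ordered():
            if seg.label == label:
                return cum, cum + seg.length
            cum += seg.length
        return None

    def to_genomic(self, offset: int) -> int:
        cum = 0
        for seg in self._ordered():
            if offset < cum + seg.length:
                within = offset - cum
                return seg.start + within if self.strand == "+" else seg.end - 1 - within
            cum += seg.length
        raise IndexError(offset)


def _splice(chain: Sequence[Segment], contig_seq: str, strand: str) -> str:
    mrna = "".join(contig_seq[seg.start : seg.end] for seg in chain)
    return reverse_complement(mrna) if strand == "-" else mrna


def untouched_nf_transcripts(mutant: MutantLocus) -> List[str]:
    """NF-flagged isoforms whose exons were not intersected by any deletion
    and whose span contains no insertion point -- the transcripts the edit
    left intact, hence not expected to be NMD substrates."""
    out = []
    for t in mutant.source_gene.transcripts:
        if not (t.flag_cds_start_nf or t.flag_cds_end_nf):
            continue
        if t.transcript_id in mutant.touched:
            continue
        out.append(t.transcript_id)
    return out


def enumerate_mutant_transcripts(
    mutant: MutantLocus, rules: Optional[SplicingRuleSet] = None
) -> List[MutantTranscript]:
    """Candidate mutant mRNAs for every wildtype isoform of the edited gene.

    Per isoform: (a) the deletion-joined transcript (flanking exons spliced
    across the removed block), (b) the splice-acceptor-retention variant
    (the residual En2_SA fragment captured between the surviving flanking
    exons), (c) a cassette-pA-truncated transcript for tm1a loci, (d)
    alternative-first-exon versions of (a)-(b), and NF-flagged isoforms the
    edit left untouched, emitted unchanged. Deduplicated by mRNA sequence
    with deterministic priority (a) < (b) < (c) < (d); capped at
    ``rules.max_variants``.
    """
    rules = rules or SplicingRuleSet()
    contig_seq = mutant.contig.sequence
    strand = mutant.strand
    sa = mutant.elements_named("En2_SA")
    sa = sa[0] if sa else None
    lacz = mutant.elements_named("lacZ")
    lacz = lacz[0] if lacz else None
    pa = mutant.elements_named("SV40_pA")
    pa = pa[0] if pa else None

    candidates: List[Tuple[int, int, MutantTranscript]] = []

    def exon_segments(exons) -> List[Segment]:
        return [Segment(f"exon{e.orig_index + 1}", e.start, e.end) for e in exons]

    def emit(order: int, src_idx: int, chain: List[Segment], events: List[str]) -> None:
        mt = MutantTranscript(
            source_isoform=mutant.source_gene.transcripts[src_idx].transcript_id,
            chain=chain,
            strand=strand,
            mrna=_splice(chain, contig_seq, strand),
            events=events,
        )
        candidates.append((order, src_idx, mt))

    all_surviving = [
        e for t in mutant.source_gene.transcripts
        for e in mutant.surviving_exons(t.transcript_id)
    ]
    gene_first_start = min((e.start for e in all_surviving), default=None)

    for src_idx, t in enumerate(mutant.source_gene.transcripts):
        tid = t.transcript_id
        surv = mutant.surviving_exons(tid)
        if not surv:
            continue
        removed = mutant.removed_exon_indices(tid)

        if (
            tid in untouched_nf_transcripts(mutant)
        ):
            emit(_EVENT_RANK[NF_UNTOUCHED], src_idx, exon_segments(surv), [NF_UNTOUCHED])
            continue

        base_variants: List[Tuple[List[Segment], List[str]]] = []
        if removed and rules.allow_exon_skip_join:
            lo, hi = min(removed), max(removed)
            has_5p = any(e.orig_index < lo for e in surv)
            has_3p = any(e.orig_index > hi for e in surv)
            if has_5p and has_3p:
                base_variants.append((exon_segments(surv), [EXON_SKIP_JOIN]))
        if sa is not None and rules.allow_sa_retention:
            up = [e for e in surv if e.end <= sa.start]
            down = [e for e in surv if e.start >= sa.end]
            if up and down:
                chain = (
                    exon_segments(up)
                    + [Segment("En2_SA", sa.start, sa.end)]
                    + exon_segments(down)
                )
                base_variants.append((chain, [SA_RETAINED]))
        for chain, events in base_variants:
            emit(_EVENT_RANK[events[0]], src_idx, chain, events)
        if (
            mutant.kind == "tm1a"
            and rules.allow_pa_truncation
            and sa is not None
            and lacz is not None
            and pa is not None
        ):
            up = [e for e in surv if e.end <= sa.start]
            if up:
                chain = exon_segments(up) + [
                    Segment("En2_SA", sa.start, sa.end),
                    Segment("lacZ", lacz.start, lacz.end),
                ]
                emit(_EVENT_RANK[PA_TRUNCATED], src_idx, chain, [PA_TRUNCATED])
        if rules.allow_alt_first_exon:
            # the alternative first exon sits a fixed offset upstream of the
            # gene's conventional exon 1; it substitutes for that exon only
            first = next(
                (
                    e
                    for e in surv
                    if e.orig_index == 0
                    and not e.truncated
                    and e.start == gene_first_start
                ),
                None,
            )
            for chain, events in base_variants:
                if first is None or chain[0].label != "exon1":
                    continue
                alt_end = first.start - rules.alt_first_exon_offset
                alt_start = alt_end - rules.alt_first_exon_length
                if alt_start < 0:
                    continue
                alt_chain = [Segment("alt_exon1", alt_start, alt_end)] + chain[1:]
                emit(
                    _EVENT_RANK[ALT_FIRST_EXON],
                    src_idx,
                    alt_chain,
                    events + [ALT_FIRST_EXON],
                )

    candidates.sort(key=lambda item: (item[0], item[1]))
    seen = set()
    out: List[MutantTranscript] = []
    for _, _, mt in candidates:
        if mt.mrna in seen:
            continue
        seen.add(mt.mrna)
        out.append(mt)
        if len(out) >= rules.max_variants:
            break
    return out
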