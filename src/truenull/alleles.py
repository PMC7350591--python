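"""Apply targeting designs to a locus: definitive null, CRISPR exon dropout,
and the KO-first (tm1a) series with Flp/Cre recombination.

The KO-first cassette follows the KOMP-CSD topology::

    FRT  En2_SA  lacZ  SV40_pA  loxP  neo  FRT  loxP   ...floxed exons...  loxP

so that Flp excises everything between the FRT pair (tm1a -> tm1c, loxP pair
around the critical exons intact) and Cre excises between the outermost loxP
sites (tm1a -> tm1b: neo and the floxed exons gone, SA-lacZ-pA retained; or
tm1c -> tm1d). These are the only legal transitions; anything else raises
:class:`RecombinationError`.

Every edit is logged with its interval and length delta; the sum of deltas
always equals the observed contig length change, and surviving exon
sequences are byte-identical to the originals.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Annotation,
    Contig,
    ExonInterval,
    GeneModel,
    TranscriptModel,
    ValidationError,
)
from .simulate import STOP_CODONS, _cap, _random_dna, _scrub

FRT_SITE = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"
LOXP_SITE = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

CASSETTE_COMPONENT_NAMES = {"En2_SA", "lacZ", "neo", "SV40_pA", "FRT", "loxP"}

ALLELE_KINDS = ("definitive_null", "crispr_dropout", "tm1a", "tm1b", "tm1c", "tm1d")


class EditError(ValueError):
    pass


class RecombinationError(EditError):
    pass


@dataclass(frozen=True)
class CassetteSpec:
    """Ordered cassette components as (name, sequence) pairs."""

    components: Tuple[Tuple[str, str], ...]
    insertion_intron: int

    def __post_init__(self) -> None:
        names = [n for n, _ in self.components]
        if not set(names) <= CASSETTE_COMPONENT_NAMES:
            raise ValidationError(f"unknown cassette components {set(names) - CASSETTE_COMPONENT_NAMES}")
        sa = dict(self.components).get("En2_SA")
        if sa is not None and "TAA" not in sa:
            raise ValidationError("En2_SA must contain a stop triplet TAA")

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.components)


def default_cassette(
    insertion_intron: int,
    seed: int = 0,
    sa_len: int = 115,
    sa_stop_offset: int = 51,
    lacz_len: int = 300,
    neo_len: int = 250,
    pa_len: int = 60,
) -> CassetteSpec:
    """Synthetic placeholder cassette sequences with real FRT/loxP sites.

    The splice-acceptor fragment defaults to 115 nt with a TAA stop planted
    at ``sa_stop_offset`` (an offset divisible by 3, i.e. in frame with a
    capture that enters the fragment on a codon boundary); component lengths
    are parameters, not constants.
    """
    rng = np.random.default_rng(seed)
    if not 1 <= sa_stop_offset <= sa_len - 4:
        raise ValidationError("sa_stop_offset outside the SA fragment interior")
    sa = _cap(_scrub(_random_dna(rng, sa_len)))
    # clear the capture frame up to the planted stop so the stop terminates it
    phase = sa_stop_offset % 3
    chars = list(sa)
    for p in range(phase, sa_stop_offset, 3):
        if "".join(chars[p : p + 3]) in STOP_CODONS:
            chars[p + 1] = "C"
    sa = "".join(chars)
    sa = sa[:sa_stop_offset] + "TAA" + sa[sa_stop_offset + 3 :]
    sa = _scrub(sa, protect=[(sa_stop_offset, sa_stop_offset + 3)])
    lacz = _cap(_scrub(_random_dna(rng, lacz_len)))
    neo = _scrub(_random_dna(rng, neo_len))
    pa = _scrub(_random_dna(rng, pa_len))
    return CassetteSpec(
        components=(
            ("FRT", FRT_SITE),
            ("En2_SA", sa),
            ("lacZ", lacz),
            ("SV40_pA", pa),
            ("loxP", LOXP_SITE),
            ("neo", neo),
            ("FRT", FRT_SITE),
            ("loxP", LOXP_SITE),
        ),
        insertion_intron=insertion_intron,
    )


@dataclass
class AlleleDesign:
    """A targeting event: what to delete / insert and where."""

    kind: str
    deleted_interval: Optional[Tuple[int, int]] = None
    floxed_exons: Optional[Tuple[int, int]] = None
    cassette: Optional[CassetteSpec] = None

    def __post_init__(self) -> None:
        if self.kind not in ALLELE_KINDS:
            raise ValidationError(f"unknown allele kind {self.kind!r}")
        if self.kind == "crispr_dropout" and self.deleted_interval is None:
            raise ValidationError("crispr_dropout requires deleted_interval (cut-site pair)")
        if self.kind in {"tm1a", "tm1b", "tm1c", "tm1d"}:
            if self.cassette is None or self.floxed_exons is None:
                raise ValidationError(f"{self.kind} requires cassette and floxed_exons")


@dataclass
class EditRecord:
    op: str
    start: int
    end: int
    delta: int

    def as_dict(self) -> dict:
        return {"op": self.op, "start": self.start, "end": self.end, "delta": self.delta}


@dataclass
class SurvivingExon:
    orig_index: int
    start: int
    end: int
    truncated: bool = False


@dataclass
class Element:
    """A retained cassette fragment on the edited contig."""

    name: str
    start: int
    end: int


@dataclass
class MutantLocus:
    """An edited locus: contig, remapped gene structure and full edit log."""

    contig: Contig
    source_gene: GeneModel
    kind: str
    exon_map: Dict[str, List[Optional[SurvivingExon]]]
    cds_map: Dict[str, Optional[int]]
    residual_elements: List[Element] = field(default_factory=list)
    edit_log: List[EditRecord] = field(default_factory=list)
    touched: set = field(default_factory=set)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_wildtype(cls, annotation: Annotation, gene_id: str) -> "MutantLocus":
        gene = annotation.genes[gene_id]
        contig = annotation.contigs[gene.contig]
        exon_map = {
            t.transcript_id: [
                SurvivingExon(i, e.start, e.end) for i, e in enumerate(t.exons)
            ]
            for t in gene.transcripts
        }
        cds_map = {t.transcript_id: t.cds_start_genomic for t in gene.transcripts}
        return cls(contig, gene, "wildtype", exon_map, cds_map)

    # -- queries ----------------------------------------------------------
    @property
    def strand(self) -> str:
        return self.source_gene.strand

    def surviving_exons(self, transcript_id: str) -> List[SurvivingExon]:
        return [e for e in self.exon_map[transcript_id] if e is not None]

    def removed_exon_indices(self, transcript_id: str) -> List[int]:
        return [
            i
            for i, e in enumerate(self.exon_map[transcript_id])
            if e is None
        ]

    def elements_named(self, name: str) -> List[Element]:
        return [el for el in self.residual_elements if el.name == name]

    @property
    def length_delta(self) -> int:
        return sum(rec.delta for rec in self.edit_log)

    @property
    def gene(self) -> GeneModel:
        """Remapped GeneModel of transcripts that retain at least one exon."""
        txs = []
        for t in self.source_gene.transcripts:
            surv = self.surviving_exons(t.transcript_id)
            if not surv:
                continue
            exons = [
                ExonInterval(self.contig.name, e.start, e.end, t.strand) for e in surv
            ]
            txs.append(
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    biotype=t.biotype,
                    exons=exons,
                    cds_start_genomic=self.cds_map[t.transcript_id],
                    cds_end_genomic=None,
                    flag_cds_start_nf=t.flag_cds_start_nf,
                    flag_cds_end_nf=t.flag_cds_end_nf,
                )
            )
        if not txs:
            raise ValidationError("no transcript survives the edit")
        return GeneModel(
            self.source_gene.gene_id, self.source_gene.symbol,
            self.source_gene.strand, txs,
        )

    # -- edit engine -------------------------------------------------------
    def _map_point(self, pos: Optional[int], start: int, end: int) -> Optional[int]:
        if pos is None:
            return None
        if pos < start:
            return pos
        if pos < end:
            return None
        return pos - (end - start)

    def _delete(self, start: int, end: int, op: str) -> None:
        if not 0 <= start <= end <= len(self.contig):
            raise EditError(f"deletion [{start}, {end}) outside contig")
        if start == end:
            self.edit_log.append(EditRecord(op, start, end, 0))
            return
        seq = self.contig.sequence
        self.contig = Contig(self.contig.name, seq[:start] + seq[end:])
        shift = end - start
        for tid, exons in self.exon_map.items():
            for i, e in enumerate(exons):
                if e is None:
                    continue
                if e.end <= start:
                    continue
                if e.start >= end:
                    e.start -= shift
                    e.end -= shift
                    continue
                self.touched.add(tid)
                if start <= e.start and e.end <= end:
                    exons[i] = None
                elif e.start < start and e.end > end:
                    e.end -= shift
                    e.truncated = True
                elif e.start < start:
                    e.end = start
                    e.truncated = True
                else:  # e.end > end
                    e.start, e.end = start, e.end - shift
                    e.truncated = True
        for tid in self.cds_map:
            self.cds_map[tid] = self._map_point(self.cds_map[tid], start, end)
        kept = []
        for el in self.residual_elements:
            if el.end <= start:
                kept.append(el)
            elif el.start >= end:
                kept.append(Element(el.name, el.start - shift, el.end - shift))
            # elements overlapping the cut are consumed
        self.residual_elements = kept
        self.edit_log.append(EditRecord(op, start, end, -shift))

    def _insert(self, pos: int, seq: str, elements: Sequence[Tuple[str, int, int]] = (),
                op: str = "insert") -> None:
        if not 0 <= pos <= len(self.contig):
            raise EditError(f"insertion point {pos} outside contig")
        for tid, exons in self.exon_map.items():
            for e in exons:
                if e is not None and e.start < pos < e.end:
                    raise EditError(f"insertion point {pos} falls inside an exon")
        shift = len(seq)
        s = self.contig.sequence
        self.contig = Contig(self.contig.name, s[:pos] + seq + s[pos:])
        for tid, exons in self.exon_map.items():
            surv = [e for e in exons if e is not None]
            if surv and surv[0].start < pos < surv[-1].end:
                self.touched.add(tid)
            for e in exons:
                if e is None:
                    continue
                if e.start >= pos:
                    e.start += shift
                    e.end += shift
        for tid, p in self.cds_map.items():
            if p is not None and p >= pos:
                self.cds_map[tid] = p + shift
        self.residual_elements = [
            el if el.end <= pos else Element(el.name, el.start + shift, el.end + shift)
            for el in self.residual_elements
        ]
        for name, rel_s, rel_e in elements:
            self.residual_elements.append(Element(name, pos + rel_s, pos + rel_e))
        self.residual_elements.sort(key=lambda el: el.start)
        self.edit_log.append(EditRecord(op, pos, pos, shift))

    # -- serialization -----------------------------------------------------
    def edit_log_json(self) -> str:
        return json.dumps(
            {
                "gene_id": self.source_gene.gene_id,
                "allele_kind": self.kind,
                "length_delta": self.length_delta,
                "edits": [rec.as_dict() for rec in self.edit_log],
                "residual_elements": [
                    {"name": el.name, "start": el.start, "end": el.end}
                    for el in self.residual_elements
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# targeting operations
# ---------------------------------------------------------------------------


def _coding_span(gene: GeneModel) -> Tuple[int, int]:
    """Genomic span from the first to the last coding exon over all isoforms."""
    starts, ends = [], []
    for t in gene.transcripts:
        if t.cds_start_genomic is None or t.cds_end_genomic is None:
            continue
        for e in t.exons:
            if e.start < t.cds_end_genomic and e.end > t.cds_start_genomic:
                starts.append(e.start)
                ends.append(e.end)
    if not starts:
        raise EditError(f"gene {gene.gene_id} has no coding exons")
    return min(starts), max(ends)


def apply_definitive_null(annotation: Annotation, gene_id: str) -> MutantLocus:
    """Delete the gene's complete coding span (first to last coding exon of
    any isoform), so no coding exon of any isoform survives."""
    m = MutantLocus.from_wildtype(annotation, gene_id)
    span = _coding_span(m.source_gene)
    m._delete(span[0], span[1], "definitive_null_deletion")
    m.kind = "definitive_null"
    return m


def apply_crispr_dropout(
    annotation: Annotation,
    gene_id: str,
    cut5: int,
    cut3: int,
    allow_exonic_cuts: bool = False,
    scar: str = "",
) -> MutantLocus:
    """NHEJ dropout between two cut sites; no scar by default."""
    if cut5 > cut3:
        raise EditError("cut5 must not exceed cut3")
    m = MutantLocus.from_wildtype(annotation, gene_id)
    if not allow_exonic_cuts:
        for e in m.source_gene.exon_union():
            for cut in (cut5, cut3):
                if e.start < cut < e.end:
                    raise EditError(
                        f"cut site {cut} lies inside exon [{e.start}, {e.end}); "
                        "set allow_exonic_cuts to permit this"
                    )
    m._delete(cut5, cut3, "crispr_dropout")
    if scar:
        m._insert(cut5, scar, op="dropout_scar")
    m.kind = "crispr_dropout"
    return m


def _intron_interval(gene: GeneModel, index: int) -> Tuple[int, int]:
    union = gene.exon_union()
    if not 0 <= index < len(union) - 1:
        raise EditError(f"intron index {index} out of range")
    return union[index].end, union[index + 1].start


def apply_tm1a(
    annotation: Annotation,
    gene_id: str,
    design: AlleleDesign,
) -> MutantLocus:
    """Insert the KO-first cassette into the named intron and flox the
    critical exon range with a downstream loxP site."""
    if design.kind != "tm1a":
        raise EditError(f"apply_tm1a called with design kind {design.kind!r}")
    cassette = design.cassette
    flox_lo, flox_hi = design.floxed_exons
    m = MutantLocus.from_wildtype(annotation, gene_id)
    if cassette.insertion_intron >= flox_lo:
        raise EditError("floxed exon range must lie downstream of the cassette intron")
    cas_lo, cas_hi = _intron_interval(m.source_gene, cassette.insertion_intron)
    cas_pos = (cas_lo + cas_hi) // 2
    lox_lo, lox_hi = _intron_interval(m.source_gene, flox_hi)
    lox_pos = (lox_lo + lox_hi) // 2
    # insert the downstream site first so the upstream coordinates stay valid
    m._insert(lox_pos, LOXP_SITE, [("loxP", 0, len(LOXP_SITE))], op="loxP_insertion")
    elements, off = [], 0
    for name, seq in cassette.components:
        elements.append((name, off, off + len(seq)))
        off += len(seq)
    m._insert(cas_pos, cassette.sequence, elements, op="cassette_insertion")
    m.kind = "tm1a"
    return m


def _excise_between(m: MutantLocus, sites: List[Element], op: str) -> None:
    first, last = sites[0], sites[-1]
    m._delete(first.end, last.end, op)


def flp_recombine(mutant: MutantLocus) -> MutantLocus:
    """tm1a -> tm1c: excise between the FRT pair (cassette gone, one FRT
    scar, loxP pair around the critical exons intact)."""
    if mutant.kind != "tm1a":
        raise RecombinationError(f"flp has no legal transition from {mutant.kind!r}")
    m = copy.deepcopy(mutant)
    frts = m.elements_named("FRT")
    if len(frts) < 2:
        raise RecombinationError("no FRT pair present")
    _excise_between(m, frts, "flp_excision")
    m.kind = "tm1c"
    return m


def cre_recombine(mutant: MutantLocus) -> MutantLocus:
    """tm1a -> tm1b (floxed exons and neo removed, SA-lacZ-pA retained) or
    tm1c -> tm1d (floxed exons removed, single loxP scar)."""
    transitions = {"tm1a": "tm1b", "tm1c": "tm1d"}
    if mutant.kind not in transitions:
        raise RecombinationError(f"cre has no legal transition from {mutant.kind!r}")
    m = copy.deepcopy(mutant)
    loxps = m.elements_named("loxP")
    if len(loxps) < 2:
        raise RecombinationError("no loxP pair present")
    _excise_between(m, loxps, "cre_excision")
    m.kind = transitions[mutant.kind]
    return m


def apply_design(annotation: Annotation, gene_id: str, design: AlleleDesign) -> MutantLocus:
    """Dispatch a design to the targeting operations; tm1b/tm1c/tm1d are
    derived states reached by recombining a tm1a locus."""
    if design.kind == "definitive_null":
        return apply_definitive_null(annotation, gene_id)
    if design.kind == "crispr_dropout":
        cut5, cut3 = design.deleted_interval
        return apply_crispr_dropout(annotation, gene_id, cut5, cut3)
    tm1a = apply_tm1a(annotation, gene_id, replace(design, kind="tm1a"))
    if design.kind == "tm1a":
        return tm1a
    if design.kind == "tm1b":
        return cre_recombine(tm1a)
    tm1c = flp_recombine(tm1a)
    if design.kind == "tm1c":
        return tm1c
    return cre_recombine(tm1c)


def write_mutant(mutant: MutantLocus, prefix: str) -> None:
    """Serialize an edited locus to FASTA + GTF + a JSON edit log."""
    from .io import write_fasta, write_gtf

    write_fasta([mutant.contig], f"{prefix}.fa")
    ann = Annotation(
        contigs={mutant.contig.name: mutant.contig},
        genes={mutant.source_gene.gene_id: mutant.gene},
        provenance=f"truenull allele {mutant.kind}",
    )
    write_gtf(ann, f"{prefix}.gtf")
    with open(f"{prefix}_edits.json", "w") as fh:
        fh.write(mutant.edit_log_json())


def rhbdf1_design(locus, kind: str, cassette_seed: int = 0) -> AlleleDesign:
    """Standard designs for the packaged multi-isoform preset locus:
    the definitive null (whole coding span), the 572-nt dropout of exons
    2-3, and the KO-first series (cassette in intron 3, exons 4-11 floxed).
    """
    if kind == "definitive_null":
        return AlleleDesign("definitive_null")
    if kind == "crispr_dropout":
        return AlleleDesign("crispr_dropout", deleted_interval=locus.crispr_dropout_cuts())
    return AlleleDesign(
        kind,
        floxed_exons=(3, 10),
        cassette=default_cassette(insertion_intron=2, seed=cassette_seed),
    )
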