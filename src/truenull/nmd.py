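"""NMD-escape classification, the incomplete-CDS census, and the per-gene
escape screen.

The decay rule is the classical exon-junction rule: a termination codon
more than ``junction_rule_nt`` (default 50) nt upstream of the last
exon-exon junction marks the transcript for nonsense-mediated decay; stops
in the last exon, within the window, or on single-exon transcripts escape.
Transcripts whose CDS is annotated incomplete (``cds_start_NF`` /
``cds_end_NF``) are treated as natural NMD escapers when the targeting
event leaves them untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .alleles import AlleleDesign, MutantLocus, apply_design
from .model import Annotation, GeneModel
from .orfs import ORFCall, StartPolicy, scan_orfs
from .transcripts import (
    NF_UNTOUCHED,
    MutantTranscript,
    SplicingRuleSet,
    enumerate_mutant_transcripts,
    untouched_nf_transcripts,
)

NMD_TARGET = "NMD_TARGET"
ESCAPE = "ESCAPE"
NO_STOP = "NO_STOP"

TRUE_NULL_LIKELY = "TRUE_NULL_LIKELY"
ESCAPE_PRONE = "ESCAPE_PRONE"

EV_NF_UNTOUCHED = "NF_UNTOUCHED"
EV_REINIT_ORF = "REINIT_ORF"
EV_NMD_ESCAPE_PRODUCT = "NMD_ESCAPE_PRODUCT"
EV_SA_RETENTION_PRODUCT = "SA_RETENTION_PRODUCT"


@dataclass(frozen=True)
class NMDPolicy:
    junction_rule_nt: int = 50
    last_exon_escape: bool = True
    nf_transcripts_escape: bool = True

    def __post_init__(self) -> None:
        if self.junction_rule_nt < 0:
            raise ValueError("junction_rule_nt must be >= 0")


@dataclass
class NMDVerdict:
    transcript_id: str
    stop_offset: Optional[int]
    dist_to_last_junction: Optional[int]  # negative if the stop is downstream
    verdict: str


def classify_stop(
    stop_offset: Optional[int], junctions: Sequence[int], policy: NMDPolicy
) -> Tuple[str, Optional[int]]:
    """Distance-rule arithmetic shared by transcript-level classification."""
    if stop_offset is None:
        return NO_STOP, None
    if not junctions:
        return ESCAPE, None
    dist = junctions[-1] - stop_offset
    if dist <= 0:
        return (ESCAPE if policy.last_exon_escape else ESCAPE), dist
    if dist > policy.junction_rule_nt:
        return NMD_TARGET, dist
    return ESCAPE, dist


def classify_nmd(
    mt: MutantTranscript, orf: ORFCall, policy: Optional[NMDPolicy] = None
) -> NMDVerdict:
    """Classify one predicted ORF on one mutant transcript."""
    policy = policy or NMDPolicy()
    verdict, dist = classify_stop(orf.stop_offset, mt.junctions(), policy)
    return NMDVerdict(
        transcript_id=mt.variant_id,
        stop_offset=orf.stop_offset,
        dist_to_last_junction=dist,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# incomplete-CDS census
# ---------------------------------------------------------------------------


@dataclass
class CensusSummary:
    n_genes: int
    n_with_nf: int
    percent: int  # nearest-integer percent, matching how the census is reported

    def as_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_with_incomplete_cds": self.n_with_nf,
            "percent": self.percent,
        }


def census_incomplete_cds(annotation: Annotation) -> CensusSummary:
    """Gene-level census of incomplete-CDS (NF-flagged) transcripts.

    A gene counts once if at least one of its protein-coding transcripts
    carries ``cds_start_NF`` or ``cds_end_NF``; the denominator is genes
    with at least one protein-coding transcript.
    """
    n_genes = 0
    n_with_nf = 0
    for gene in annotation.genes.values():
        coding = [t for t in gene.transcripts if t.biotype == "protein_coding"]
        if not coding:
            continue
        n_genes += 1
        if any(t.flag_cds_start_nf or t.flag_cds_end_nf for t in coding):
            n_with_nf += 1
    if n_genes == 0:
        raise ValueError("annotation contains no protein-coding genes")
    return CensusSummary(n_genes, n_with_nf, round(100 * n_with_nf / n_genes))


# ---------------------------------------------------------------------------
# escape screen
# ---------------------------------------------------------------------------


@dataclass
class EscapeEvidence:
    type: str
    transcript_id: str
    detail: Dict = field(default_factory=dict)


@dataclass
class EscapeReport:
    gene_id: str
    design_kind: str
    evidence: List[EscapeEvidence]
    classification: str

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "gene_id": self.gene_id,
            "design_kind": self.design_kind,
            "classification": self.classification,
            "evidence": [
                {"type": ev.type, "transcript_id": ev.transcript_id, **ev.detail}
                for ev in self.evidence
            ],
        }

    def evidence_types(self) -> set:
        return {ev.type for ev in self.evidence}


def screen_allele(
    mutant: MutantLocus,
    transcripts: Sequence[MutantTranscript],
    start_policy: Optional[StartPolicy] = None,
    nmd_policy: Optional[NMDPolicy] = None,
) -> EscapeReport:
    """Collect escape evidence for one edited gene.

    Evidence classes: (1) NF-flagged isoforms the edit left untouched;
    (2) reinitiation ORFs of at least ``min_orf_codons`` on a mutant
    transcript whose stop escapes NMD (from the annotated canonical start
    the evidence is typed NMD_ESCAPE_PRODUCT instead); (3) ORFs terminating
    inside a retained En2 splice-acceptor fragment, reported with their NMD
    verdict regardless of it -- the observed retention products translate
    despite a junction-rule target verdict.
    """
    start_policy = start_policy or StartPolicy()
    nmd_policy = nmd_policy or NMDPolicy()
    evidence: List[EscapeEvidence] = []
    seen = set()

    def add(ev_type: str, tid: str, detail: Dict) -> None:
        key = (ev_type, tid, detail.get("start_offset"))
        if key not in seen:
            seen.add(key)
            evidence.append(EscapeEvidence(ev_type, tid, detail))

    if nmd_policy.nf_transcripts_escape:
        for tid in untouched_nf_transcripts(mutant):
            add(EV_NF_UNTOUCHED, tid, {})

    canonical = mutant.cds_map
    for mt in transcripts:
        if NF_UNTOUCHED in mt.events:
            continue  # already covered as untouched-NF evidence
        sa_span = mt.segment_span("En2_SA")
        for orf in scan_orfs(mt.mrna, start_policy, mt.variant_id):
            verdict = classify_nmd(mt, orf, nmd_policy)
            detail = {
                "start_offset": orf.start_offset,
                "start_codon": orf.start_codon,
                "start_genomic": mt.to_genomic(orf.start_offset),
                "n_codons": orf.n_codons,
                "mass_kda": orf.mass_kda,
                "nmd_verdict": verdict.verdict,
                "events": list(mt.events),
            }
            if (
                sa_span
                and orf.stop_offset is not None
                and sa_span[0] <= orf.stop_offset < sa_span[1]
            ):
                add(EV_SA_RETENTION_PRODUCT, mt.variant_id, detail)
                continue
            if verdict.verdict == ESCAPE and orf.n_codons >= start_policy.min_orf_codons:
                src_cds = canonical.get(mt.source_isoform)
                ev_type = (
                    EV_NMD_ESCAPE_PRODUCT
                    if src_cds is not None
                    and mt.to_genomic(orf.start_offset) == src_cds
                    else EV_REINIT_ORF
                )
                add(ev_type, mt.variant_id, detail)

    classification = ESCAPE_PRONE if evidence else TRUE_NULL_LIKELY
    return EscapeReport(
        gene_id=mutant.source_gene.gene_id,
        design_kind=mutant.kind,
        evidence=evidence,
        classification=classification,
    )


def run_screen(
    annotation: Annotation,
    gene_id: str,
    design: AlleleDesign,
    rules: Optional[SplicingRuleSet] = None,
    start_policy: Optional[StartPolicy] = None,
    nmd_policy: Optional[NMDPolicy] = None,
) -> Tuple[MutantLocus, List[MutantTranscript], EscapeReport]:
    """Apply a design, enumerate mutant transcripts and screen them."""
    mutant = apply_design(annotation, gene_id, design)
    transcripts = enumerate_mutant_transcripts(mutant, rules)
    report = screen_allele(mutant, transcripts, start_policy, nmd_policy)
    return mutant, transcripts, report


@dataclass
class ScreenSummary:
    n_reports: int
    per_design: Dict[str, Dict[str, int]]  # kind -> {n, escape_prone, percent}

    def as_dict(self) -> dict:
        return {"n_reports": self.n_reports, "per_design": self.per_design}


def summarize_screen(reports: Sequence[EscapeReport]) -> ScreenSummary:
    """Per-design escape-prone counts with nearest-integer percents."""
    if not reports:
        raise ValueError("no reports to summarize")
    per: Dict[str, Dict[str, int]] = {}
    for rep in reports:
        entry = per.setdefault(rep.design_kind, {"n": 0, "escape_prone": 0})
        entry["n"] += 1
        if rep.classification == ESCAPE_PRONE:
            entry["escape_prone"] += 1
    for entry in per.values():
        entry["percent"] = round(100 * entry["escape_prone"] / entry["n"])
    return ScreenSummary(len(reports), per)
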