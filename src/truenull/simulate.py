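"""Synthetic genomes, annotations and viability tables.

Every downstream stage of the pipeline (allele engineering, transcript
enumeration, ORF scanning, the NMD / incomplete-CDS screen) is exercised on
loci built here, so the generators plant their features *exactly*: counts
are round(n x fraction), never Bernoulli draws, and every asserted start
codon really occurs at the stated offset.

Sequence hygiene conventions (documented in docs/methods.md):

* exon, intron and flank sequences are generated ATG-free, so the only AUG
  (or near-cognate) starts a scanner can find are the planted ones;
* the first and last base of every exon-like segment is fixed to ``C``, so
  no start or stop triplet can ever span a splice junction (ATG/TAA/TAG/TGA
  contain no C);
* introns begin ``GT`` and end ``AG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    Annotation,
    Contig,
    ExonInterval,
    GeneModel,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)

STOP_CODONS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _scrub(seq: str, words: Sequence[str] = ("ATG",), protect: Sequence[Tuple[int, int]] = ()) -> str:
    """Destroy every occurrence of ``words`` by setting its middle base to C.

    C appears in none of the start/stop triplets of interest, so a single
    left-to-right pass cannot create new occurrences. Occurrences overlapping
    a protected [start, end) range are left alone.
    """
    chars = list(seq)
    for w in words:
        i = 0
        while i <= len(chars) - len(w):
            if "".join(chars[i : i + len(w)]) == w:
                if any(i < e and i + len(w) > s for s, e in protect):
                    i += 1
                    continue
                chars[i + len(w) // 2] = "C"
            i += 1
    return "".join(chars)


def _cap(seq: str) -> str:
    """Fix the terminal bases of an exon-like segment to C (junction safety)."""
    if len(seq) < 2:
        raise ValidationError("exon segments must be at least 2 nt")
    return "C" + seq[1:-1] + "C"


def _make_exon(rng: np.random.Generator, n: int) -> str:
    return _cap(_scrub(_random_dna(rng, n)))


def _make_intron(rng: np.random.Generator, n: int) -> str:
    if n < 6:
        raise ValidationError(f"intron length {n} too short for GT..AG")
    return "GT" + _scrub(_random_dna(rng, n - 4)) + "AG"


def _plant(seq: str, offset: int, codon: str) -> str:
    """Plant ``codon`` at an interior offset of an exon sequence."""
    if offset < 1 or offset + len(codon) > len(seq) - 1:
        raise ValidationError(
            f"codon placement at offset {offset} overlaps an exon boundary"
        )
    return seq[:offset] + codon + seq[offset + len(codon) :]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class IsoformSpec:
    """One isoform over a locus: which exons, and where translation starts.

    ``start_exon_codon`` is (exon index, offset within exon in transcript
    orientation, codon string); ``nf5``/``nf3`` mark the transcript as having
    a 5'- / 3'-incomplete CDS (no asserted start / stop codon).
    """

    exon_indices: Sequence[int]
    start_exon_codon: Optional[Tuple[int, int, str]] = None
    nf5: bool = False
    nf3: bool = False
    transcript_id: Optional[str] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        idx = list(self.exon_indices)
        if not idx or any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("exon_indices must be nonempty, strictly increasing")
        if self.nf5 and self.start_exon_codon is not None:
            raise ValidationError("a 5'-incomplete isoform cannot assert a start codon")


@dataclass
class LocusSpec:
    n_exons: int
    exon_lengths: Sequence[int]
    intron_lengths: Sequence[int]
    isoforms: Sequence[IsoformSpec]
    strand: str = "+"
    seed: int = 0
    flank: int = 400
    gene_id: str = "gene1"
    symbol: str = "Gene1"
    contig_name: str = "chr_sim"
    extra_codons: Sequence[Tuple[int, int, str]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.exon_lengths) != self.n_exons:
            raise ValidationError("exon_lengths must have n_exons entries")
        if len(self.intron_lengths) != self.n_exons - 1:
            raise ValidationError("intron_lengths must have n_exons - 1 entries")
        if any(l <= 0 for l in list(self.exon_lengths) + list(self.intron_lengths)):
            raise ValidationError("all lengths must be positive")
        for iso in self.isoforms:
            if any(i >= self.n_exons for i in iso.exon_indices):
                raise ValidationError("isoform references a missing exon")


@dataclass
class LocusLayout:
    """Genomic geometry of a simulated locus (plus-strand coordinates)."""

    contig_name: str
    flank: int
    exon_intervals: List[Tuple[int, int]]
    intron_intervals: List[Tuple[int, int]]
    strand: str

    def exon(self, i: int) -> Tuple[int, int]:
        return self.exon_intervals[i]

    def intron(self, i: int) -> Tuple[int, int]:
        return self.intron_intervals[i]


@dataclass
class SimulatedLocus:
    annotation: Annotation
    layout: LocusLayout

    @property
    def contig(self) -> Contig:
        return self.annotation.contigs[self.layout.contig_name]

    @property
    def gene(self) -> GeneModel:
        return next(iter(self.annotation.genes.values()))


# ---------------------------------------------------------------------------
# generate_locus
# ---------------------------------------------------------------------------


def _assemble(
    spec: LocusSpec,
    exon_seqs: List[str],
    intron_seqs: List[str],
    up: str,
    down: str,
) -> SimulatedLocus:
    parts = [up]
    exon_iv: List[Tuple[int, int]] = []
    intron_iv: List[Tuple[int, int]] = []
    pos = len(up)
    for i, es in enumerate(exon_seqs):
        exon_iv.append((pos, pos + len(es)))
        parts.append(es)
        pos += len(es)
        if i < len(intron_seqs):
            intron_iv.append((pos, pos + len(intron_seqs[i])))
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(down)
    contig = Contig(spec.contig_name, "".join(parts))

    transcripts = []
    for k, iso in enumerate(spec.isoforms):
        tid = iso.transcript_id or f"{spec.gene_id}_t{k + 1:02d}"
        exons = [
            ExonInterval(spec.contig_name, *exon_iv[i], spec.strand)
            for i in iso.exon_indices
        ]
        cds_start = cds_end = None
        if iso.start_exon_codon is not None:
            ei, off, codon = iso.start_exon_codon
            s, e = exon_iv[ei]
            if spec.strand == "+":
                g = s + off
                cds_start = g
                cds_end = exon_iv[iso.exon_indices[-1]][1]
            else:
                g = e - off - len(codon)
                cds_start = exon_iv[iso.exon_indices[0]][0]
                cds_end = g + len(codon)
        elif iso.nf5 or iso.nf3:
            cds_start = exons[0].start
            cds_end = exons[-1].end
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=spec.gene_id,
                biotype=iso.biotype,
                exons=exons,
                cds_start_genomic=cds_start,
                cds_end_genomic=cds_end,
                flag_cds_start_nf=iso.nf5,
                flag_cds_end_nf=iso.nf3,
            )
        )
    gene = GeneModel(spec.gene_id, spec.symbol, spec.strand, transcripts)
    ann = Annotation(
        contigs={contig.name: contig},
        genes={gene.gene_id: gene},
        provenance=f"truenull.simulate seed={spec.seed}",
    )
    ann.validate()
    layout = LocusLayout(spec.contig_name, spec.flank, exon_iv, intron_iv, spec.strand)
    return SimulatedLocus(ann, layout)


def generate_locus(spec: LocusSpec) -> SimulatedLocus:
    """Build a single-gene locus with the requested exon/intron geometry.

    Deterministic for a fixed seed. Planted start codons really occur at the
    stated offsets; everything else is AUG-free so scanners only find what
    was planted.
    """
    rng = np.random.default_rng(spec.seed)
    exon_seqs = [_make_exon(rng, n) for n in spec.exon_lengths]
    intron_seqs = [_make_intron(rng, n) for n in spec.intron_lengths]
    up = _scrub(_random_dna(rng, spec.flank))
    down = _scrub(_random_dna(rng, spec.flank))

    plants: List[Tuple[int, int, str]] = list(spec.extra_codons)
    for iso in spec.isoforms:
        if iso.start_exon_codon is not None:
            plants.append(iso.start_exon_codon)
    for ei, off, codon in plants:
        seq = exon_seqs[ei]
        if spec.strand == "-":
            codon_g = reverse_complement(codon)
            off_g = len(seq) - off - len(codon)
        else:
            codon_g, off_g = codon, off
        exon_seqs[ei] = _plant(seq, off_g, codon_g)
    # re-scrub around plants: a planted codon must not create a stray ATG
    for i, seq in enumerate(exon_seqs):
        protect = [
            (off if spec.strand == "+" else len(seq) - off - len(c), 0)
            for ei, off, c in plants
            if ei == i
        ]
        protect = [(s, s + 3) for s, _ in protect]
        exon_seqs[i] = _scrub(seq, protect=protect)
    return _assemble(spec, exon_seqs, intron_seqs, up, down)


# ---------------------------------------------------------------------------
# Rhbdf1-like preset
# ---------------------------------------------------------------------------

#: 18 exon lengths (nt). Arbitrary, but chosen so that (i) the A7 dropout of
#: exons 2-3 measures exactly 572 nt of genomic sequence, (ii) the joined
#: exon3|exon12 RT-PCR product is 209 nt with the packaged primers, and
#: (iii) exons 4..11 sum to 1100 nt (not a multiple of 3), so the post-Cre
#: exon3->exon12 join is frameshifted, as needed for the escape logic.
PRESET_EXON_LENGTHS = [200, 150, 142, 400, 90, 100, 110, 95, 105, 115, 85,
                       130, 140, 120, 110, 100, 90, 300]
PRESET_INTRON_LENGTHS = [150, 80, 150] + [100] * 14
PRESET_FLANK = 400

CANONICAL_START = (1, 31, "ATG")   # exon 2, interior, frame anchor
EXON4_REINIT_ATG = (3, 60, "ATG")  # downstream in-frame AUG (offset 60 = 0 mod 3)
CGC_START = (12, 30, "CGC")        # non-AUG start isoform, in canonical frame
CANONICAL_STOP = (17, 250, "TAA")  # in-frame stop in the last exon
ALT_EXON1_OFFSET = 199             # alternative first exon, this far upstream
ALT_EXON1_LENGTH = 100


@dataclass
class RhbdfLikeLocus(SimulatedLocus):
    """The packaged 18-exon multi-isoform locus.

    Isoforms:

    * ``RHB201`` - full-length, AUG start in exon 2, stop in exon 18;
    * ``RHB206`` - exons 14-18 only, 5'-incomplete CDS (``cds_start_NF``);
    * ``RHB207`` - exons 13-18, non-AUG (CGC) start codon.

    Landmarks (genomic coordinates) are exposed for building allele designs
    and primers; exon 4 carries an in-frame AUG downstream of the canonical
    start, and an alternative first exon window sits 199 bp upstream of
    exon 1.
    """

    landmarks: Dict[str, int] = field(default_factory=dict)

    # -- allele-design helpers -------------------------------------------
    def crispr_dropout_cuts(self) -> Tuple[int, int]:
        """Intronic cut pair excising exons 2-3 as a 572-nt dropout."""
        i0 = self.layout.intron(0)
        i2 = self.layout.intron(2)
        return i0[0] + 50, i2[0] + 100

    def genotyping_primer_sites(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """Genomic primer sites flanking exons 2-3 (1300-nt wildtype product)."""
        cut5, cut3 = self.crispr_dropout_cuts()
        return (cut5 - 300, cut5 - 280), (cut3 + 408, cut3 + 428)

    def rtpcr_primer_sites(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        """Exon-3 forward / exon-12 reverse sites (209-nt cassette-free join)."""
        e2 = self.layout.exon(2)
        e11 = self.layout.exon(11)
        return (e2[0] + 33, e2[0] + 53), (e11[0] + 80, e11[0] + 100)

    @property
    def alt_exon1_interval(self) -> Tuple[int, int]:
        s = self.layout.exon(0)[0] - ALT_EXON1_OFFSET
        return s - ALT_EXON1_LENGTH, s


def _clean_frame(
    exon_seqs: List[str],
    exon_indices: Sequence[int],
    start: Tuple[int, int],
) -> List[str]:
    """Remove in-frame stop codons along a plus-strand isoform's frame.

    Codons spanning junctions contain a capped C base and can never be
    stops, so only fully-in-exon codons need attention.
    """
    ei0, off0 = start
    chain = list(exon_indices)
    k0 = chain.index(ei0)
    pos = off0
    for k in range(k0, len(chain)):
        ei = chain[k]
        seq = exon_seqs[ei]
        while pos + 3 <= len(seq):
            if seq[pos : pos + 3] in STOP_CODONS:
                seq = seq[:pos] + seq[pos] + "C" + seq[pos + 2 :]
            pos += 3
        exon_seqs[ei] = seq
        overhang = len(seq) - pos  # 0..2 bases feeding the spanning codon
        if k + 1 < len(chain):
            pos = (3 - overhang) % 3
            # spanning codons are junction-capped, never stops; skip them
            if overhang:
                pos = 3 - overhang
    return exon_seqs


def rhbdf1_like_preset(seed: int = 0) -> RhbdfLikeLocus:
    """Build the packaged multi-isoform locus (deterministic per seed).

    Two different seeds give the identical gene architecture (coordinates,
    planted codons) with different background sequence.
    """
    rng = np.random.default_rng(seed)
    exon_seqs = [_make_exon(rng, n) for n in PRESET_EXON_LENGTHS]
    intron_seqs = [_make_intron(rng, n) for n in PRESET_INTRON_LENGTHS]
    up = _scrub(_random_dna(rng, PRESET_FLANK))
    down = _scrub(_random_dna(rng, PRESET_FLANK))

    for ei, off, codon in (CANONICAL_START, EXON4_REINIT_ATG, CGC_START):
        exon_seqs[ei] = _plant(exon_seqs[ei], off, codon)
    # canonical reading frame: scrub stops from the exon-2 AUG through exon 18
    exon_seqs = _clean_frame(
        exon_seqs, list(range(1, 18)), (CANONICAL_START[0], CANONICAL_START[1])
    )
    ei, off, codon = CANONICAL_STOP
    exon_seqs[ei] = _plant(exon_seqs[ei], off, codon)
    # stray-ATG hygiene after planting, protecting the intended codons
    protected = {1: [(31, 34)], 3: [(60, 63)], 12: [(30, 33)], 17: [(250, 253)]}
    for i, seq in enumerate(exon_seqs):
        exon_seqs[i] = _scrub(seq, protect=protected.get(i, []))

    # alternative first exon window in the upstream flank, junction-capped
    alt_start = PRESET_FLANK - ALT_EXON1_OFFSET - ALT_EXON1_LENGTH
    alt_end = PRESET_FLANK - ALT_EXON1_OFFSET
    up = up[:alt_start] + _cap(up[alt_start:alt_end]) + up[alt_end:]

    spec = LocusSpec(
        n_exons=18,
        exon_lengths=PRESET_EXON_LENGTHS,
        intron_lengths=PRESET_INTRON_LENGTHS,
        isoforms=[
            IsoformSpec(range(18), start_exon_codon=CANONICAL_START,
                        transcript_id="RHB201"),
            IsoformSpec(range(13, 18), nf5=True, transcript_id="RHB206"),
            IsoformSpec(range(12, 18), start_exon_codon=CGC_START,
                        transcript_id="RHB207"),
        ],
        strand="+",
        seed=seed,
        flank=PRESET_FLANK,
        gene_id="GENE_RHB",
        symbol="Rhbdf1_like",
        contig_name="chr_rhb",
    )
    sim = _assemble(spec, exon_seqs, intron_seqs, up, down)
    lay = sim.layout
    landmarks = {
        "canonical_start": lay.exon(1)[0] + 31,
        "exon4_reinit_atg": lay.exon(3)[0] + 60,
        "cgc_start": lay.exon(12)[0] + 30,
        "canonical_stop": lay.exon(17)[0] + 250,
    }
    return RhbdfLikeLocus(sim.annotation, sim.layout, landmarks)


# ---------------------------------------------------------------------------
# whole-genome and viability simulators
# ---------------------------------------------------------------------------


@dataclass
class GenomeSimParams:
    n_genes: int
    frac_incomplete_cds: float = 0.35
    exon_length_range: Tuple[int, int] = (60, 200)
    intron_length_range: Tuple[int, int] = (60, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not 0.0 <= self.frac_incomplete_cds <= 1.0:
            raise ValidationError("frac_incomplete_cds must be in [0, 1]")


def generate_genome(params: GenomeSimParams) -> Annotation:
    """A multi-gene annotation where exactly round(n x frac) genes carry at
    least one NF-flagged (incomplete-CDS) transcript. One contig per gene."""
    rng = np.random.default_rng(params.seed)
    n_nf = int(round(params.n_genes * params.frac_incomplete_cds))
    nf_genes = set(rng.choice(params.n_genes, size=n_nf, replace=False).tolist())
    ann = Annotation(provenance=f"truenull.generate_genome seed={params.seed}")
    lo_e, hi_e = params.exon_length_range
    lo_i, hi_i = params.intron_length_range
    for g in range(params.n_genes):
        n_exons = 3
        exon_lengths = [int(x) for x in rng.integers(lo_e, hi_e + 1, size=n_exons)]
        intron_lengths = [int(x) for x in rng.integers(lo_i, hi_i + 1, size=n_exons - 1)]
        isoforms = [IsoformSpec(range(n_exons), start_exon_codon=(0, 9, "ATG"))]
        if g in nf_genes:
            isoforms.append(IsoformSpec([n_exons - 1], nf5=True))
        spec = LocusSpec(
            n_exons=n_exons,
            exon_lengths=exon_lengths,
            intron_lengths=intron_lengths,
            isoforms=isoforms,
            seed=int(rng.integers(0, 2**31 - 1)),
            flank=100,
            gene_id=f"g{g + 1:04d}",
            symbol=f"Gene{g + 1:04d}",
            contig_name=f"chr_g{g + 1:04d}",
        )
        sim = generate_locus(spec)
        ann.contigs.update(sim.annotation.contigs)
        ann.genes.update(sim.annotation.genes)
    return ann


@dataclass
class ViabilitySimParams:
    n_strains: int
    conflict_rate: float = 0.04
    class_probs: Tuple[float, float, float] = (0.5, 0.25, 0.25)  # viable, subviable, lethal
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conflict_rate <= 1.0:
            raise ValidationError("conflict_rate must be in [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValidationError("class_probs must sum to 1")


VIABILITY_CLASSES = ("viable", "subviable", "lethal")


def generate_viability_table(params: ViabilitySimParams) -> pd.DataFrame:
    """Two allele rows per gene (tm1a-or-em first, tm1b second) with exactly
    round(n x conflict_rate) genes discordant between the two rows."""
    rng = np.random.default_rng(params.seed)
    n_conf = int(round(params.n_strains * params.conflict_rate))
    conflicted = set(rng.choice(params.n_strains, size=n_conf, replace=False).tolist())
    rows = []
    for i in range(params.n_strains):
        gene = f"Gene{i + 1:04d}"
        first_label = "tm1a" if rng.random() < 0.7 else f"em{int(rng.integers(1, 3))}"
        c1 = VIABILITY_CLASSES[
            int(rng.choice(3, p=np.asarray(params.class_probs)))
        ]
        if i in conflicted:
            others = [c for c in VIABILITY_CLASSES if c != c1]
            c2 = others[int(rng.integers(0, 2))]
        else:
            c2 = c1
        rows.append({"gene_symbol": gene, "allele_label": first_label,
                     "phenotype_class": c1})
        rows.append({"gene_symbol": gene, "allele_label": "tm1b",
                     "phenotype_class": c2})
    return pd.DataFrame(rows)
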