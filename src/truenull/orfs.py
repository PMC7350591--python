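"""Translation-start scanning, translation and product mass.

The scanner enumerates *all* candidate starts (leaky-scanning view): every
occurrence of every policy codon opens a reading frame that runs to the
first in-frame stop. Non-AUG initiators (near-cognates, and CGC as used by
some 5'-incomplete isoforms) are decoded as initiator methionine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

STOP_CODONS = ("TAA", "TAG", "TGA")

#: near-cognate start codons (one mismatch from AUG) plus CGC, which is used
#: as a natural non-AUG initiator by some 5'-incomplete isoforms
NEAR_COGNATE_STARTS = ("CTG", "GTG", "ACG", "ATT", "ATA", "ATC", "CGC")

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class StartPolicy:
    codon_set: Tuple[str, ...] = ("ATG",)
    min_orf_codons: int = 50

    def __post_init__(self) -> None:
        if self.min_orf_codons < 1:
            raise ValueError("min_orf_codons must be >= 1")
        for c in self.codon_set:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"bad start codon {c!r}")

    @classmethod
    def extended(cls, min_orf_codons: int = 50) -> "StartPolicy":
        """AUG plus the near-cognate / non-AUG start set."""
        return cls(("ATG",) + NEAR_COGNATE_STARTS, min_orf_codons)


@dataclass
class ORFCall:
    transcript_id: str
    start_offset: int
    start_codon: str
    stop_offset: Optional[int]  # offset of the stop triplet; None = no stop
    n_codons: int  # incl. start, excl. stop
    peptide: str
    mass_kda: Optional[float]
    short_orf: bool = False

    @property
    def no_stop(self) -> bool:
        return self.stop_offset is None


def translate(orf_region: str, initiator_codons: Sequence[str] = ("ATG",)) -> str:
    """Standard-code translation of a stop-free coding region.

    The first codon is rendered as initiator Met when it belongs to
    ``initiator_codons`` (the biology of initiator-tRNA delivery, regardless
    of the codon identity); codons containing N translate to X.
    """
    if not orf_region or len(orf_region) % 3:
        raise ValueError(f"region length {len(orf_region)} not divisible by 3")
    peptide = str(Seq(orf_region).translate())
    if orf_region[:3] in initiator_codons:
        peptide = "M" + peptide[1:]
    return peptide


def average_mass(peptide: str) -> float:
    """Average (not monoisotopic) molecular mass of a peptide, in kDa."""
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)}")
    return molecular_weight(peptide, seq_type="protein", monoisotopic=False) / 1000.0


def monoisotopic_mass(peptide: str) -> float:
    if not peptide or set(peptide) - STANDARD_AA:
        raise ValueError("peptide must be nonempty over the 20 standard residues")
    return molecular_weight(peptide, seq_type="protein", monoisotopic=True) / 1000.0


def scan_orfs(
    mrna: str, policy: Optional[StartPolicy] = None, transcript_id: str = ""
) -> List[ORFCall]:
    """All candidate ORFs in an mRNA under a start-codon policy.

    Every occurrence of a policy codon is reported with the reading frame
    running to the first in-frame stop among TAA/TAG/TGA; ORFs without a
    stop are flagged; ORFs shorter than ``min_orf_codons`` are flagged but
    retained, never silently filtered. Sorted by start offset.
    """
    policy = policy or StartPolicy()
    if len(mrna) < 3:
        raise ValueError("mRNA shorter than one codon")
    mrna = mrna.upper()
    calls: List[ORFCall] = []
    for i in range(len(mrna) - 2):
        codon = mrna[i : i + 3]
        if codon not in policy.codon_set:
            continue
        stop = None
        j = i + 3
        while j + 3 <= len(mrna):
            if mrna[j : j + 3] in STOP_CODONS:
                stop = j
                break
            j += 3
        end = stop if stop is not None else i + 3 * ((len(mrna) - i) // 3)
        region = mrna[i:end]
        peptide = translate(region, policy.codon_set) if region else ""
        try:
            mass = round(average_mass(peptide), 5) if peptide else None
        except ValueError:
            mass = None  # N-containing codons translate to X; no defined mass
        n_codons = len(region) // 3
        calls.append(
            ORFCall(
                transcript_id=transcript_id,
                start_offset=i,
                start_codon=codon,
                stop_offset=stop,
                n_codons=n_codons,
                peptide=peptide,
                mass_kda=mass,
                short_orf=n_codons < policy.min_orf_codons,
            )
        )
    return calls
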