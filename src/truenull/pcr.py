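"""In-silico PCR: exact-match primer binding, gel-size product arithmetic.

Binding is exact (0 mismatches) because the assays this models are
presence/size assays; product length is inclusive of both primers, the
standard gel-size convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Union

from .model import Contig, reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    """forward is plus-strand sense; reverse is given 5'->3' on the
    opposite strand (i.e., it binds as its reverse complement)."""

    forward: str
    reverse: str
    template_kind: str = "genomic"

    def __post_init__(self) -> None:
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 nt")
        if self.template_kind not in {"genomic", "cdna"}:
            raise ValueError(f"bad template_kind {self.template_kind!r}")


@dataclass
class AmpliconPrediction:
    template_id: str
    products: List[int]  # lengths, ascending; empty list = no band


def _find_all(template: str, query: str) -> List[int]:
    hits, i = [], template.find(query)
    while i != -1:
        hits.append(i)
        i = template.find(query, i + 1)
    return hits


def insilico_pcr(
    template: Union[str, Contig],
    primers: PrimerPair,
    max_product: int = 10_000,
    template_id: str = "template",
) -> AmpliconPrediction:
    """Every forward-site x reverse-site pairing with the forward site 5' of
    the reverse site and a span of at most ``max_product`` nt, reported as
    product lengths from the forward 5' end to the reverse 3' end inclusive."""
    if isinstance(template, Contig):
        template_id = template.name
        template = template.sequence
    template = template.upper()
    fwd_sites = _find_all(template, primers.forward.upper())
    rev_sites = _find_all(template, reverse_complement(primers.reverse.upper()))
    rev_len = len(primers.reverse)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r >= f + len(primers.forward):
                length = r + rev_len - f
                if length <= max_product:
                    products.append(length)
    return AmpliconPrediction(template_id=template_id, products=sorted(products))
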