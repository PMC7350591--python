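"""Readers and writers for FASTA and GTF/GFF3 (Ensembl dialect).

FASTA goes through Biopython SeqIO (60-column wrap on write); GTF/GFF3
parsing goes through gffutils with an in-memory database. The GTF writer is
local because it must emit a single canonical attribute order so that
outputs are bit-stable.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Annotation,
    Contig,
    ExonInterval,
    GeneModel,
    TranscriptModel,
    ValidationError,
)


class FastaParseError(ValueError):
    pass


class GtfParseError(ValueError):
    pass


def read_fasta(path: str) -> Dict[str, Contig]:
    """Read a multi-record FASTA into a Contig collection (file order).

    Sequences are uppercased and RNA U is mapped to T; characters outside
    {A,C,G,T,N,U} raise a parse error naming the offending line.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaParseError(f"{path}:1: expected '>' header, got {first[:20]!r}")
    allowed = set("ACGTNU")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") or not line.strip():
                continue
            bad = set(line.strip().upper()) - allowed
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: invalid sequence character(s) {sorted(bad)}"
                )
    contigs: Dict[str, Contig] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in contigs:
            raise FastaParseError(f"duplicate FASTA record {rec.id!r}")
        contigs[rec.id] = Contig(name=rec.id, sequence=seq)
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs
    ]
    SeqIO.write(records, path, "fasta")  # wraps at 60 columns


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_NF_START_TAGS = {"cds_start_NF", "mRNA_start_NF"}
_NF_END_TAGS = {"cds_end_NF", "mRNA_end_NF"}


def _tags(attrs) -> List[str]:
    out = list(attrs.get("tag", []))
    # GFF3 dumps sometimes carry the NF marker as a bare attribute key
    for syn in _NF_START_TAGS | _NF_END_TAGS:
        if syn in attrs and syn not in out:
            out.append(syn)
    return out


def read_gtf(path: str, dialect: str = "ensembl-gtf") -> Annotation:
    """Read Ensembl-dialect GTF (or GFF3) into an Annotation without sequences.

    1-based inclusive file coordinates become internal 0-based half-open.
    Ensembl ``tag "cds_start_NF"`` / ``tag "cds_end_NF"`` attributes populate
    the transcript NF flags (GFF3: values of the ``tag`` attribute list, with
    ``mRNA_start_NF`` accepted as a synonym).
    """
    if dialect not in {"ensembl-gtf", "gff3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - passthrough context
        raise GtfParseError(f"failed to parse {path}: {exc}") from exc

    tx_types = {"transcript", "mRNA"}
    transcripts: Dict[str, dict] = {}
    gene_meta: Dict[str, dict] = {}

    def tx_id(feat) -> str:
        if dialect == "gff3":
            if feat.featuretype in tx_types:
                return feat.id
            return feat.attributes["Parent"][0]
        return feat.attributes["transcript_id"][0]

    for feat in db.all_features(order_by=("seqid", "start")):
        attrs = feat.attributes
        if feat.featuretype == "gene":
            gid = feat.id if dialect == "gff3" else attrs["gene_id"][0]
            name = attrs.get("gene_name", attrs.get("Name", [gid]))[0]
            gene_meta[gid] = {"symbol": name}
            continue
        if feat.featuretype in tx_types:
            tid = feat.id if dialect == "gff3" else attrs["transcript_id"][0]
            if dialect == "gff3":
                gid = attrs["Parent"][0]
                biotype = attrs.get("biotype", ["protein_coding"])[0]
            else:
                gid = attrs["gene_id"][0]
                biotype = attrs.get(
                    "transcript_biotype", attrs.get("biotype", ["protein_coding"])
                )[0]
            entry = transcripts.setdefault(tid, _new_tx(tid))
            entry.update(gene_id=gid, biotype=biotype)
            tags = _tags(attrs)
            entry["nf5"] = entry["nf5"] or bool(set(tags) & _NF_START_TAGS)
            entry["nf3"] = entry["nf3"] or bool(set(tags) & _NF_END_TAGS)
            continue
        if feat.featuretype == "exon":
            entry = transcripts.setdefault(tx_id(feat), _new_tx(tx_id(feat)))
            entry["exons"].append(
                ExonInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
            entry.setdefault("gene_id", feat.attributes.get("gene_id", [None])[0])
            continue
        if feat.featuretype == "CDS":
            entry = transcripts.setdefault(tx_id(feat), _new_tx(tx_id(feat)))
            entry["cds"].append((feat.start - 1, feat.end))

    genes: Dict[str, GeneModel] = {}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tid, entry in transcripts.items():
        if entry["cds"] and not entry["exons"]:
            raise GtfParseError(f"transcript {tid} has CDS but no exons")
        if not entry["exons"]:
            raise GtfParseError(f"transcript {tid} has no exon features")
        exons = sorted(entry["exons"], key=lambda e: e.start)
        cds_start = min(s for s, _ in entry["cds"]) if entry["cds"] else None
        cds_end = max(e for _, e in entry["cds"]) if entry["cds"] else None
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=entry["gene_id"],
            biotype=entry["biotype"],
            exons=exons,
            cds_start_genomic=cds_start,
            cds_end_genomic=cds_end,
            flag_cds_start_nf=entry["nf5"],
            flag_cds_end_nf=entry["nf3"],
        )
        by_gene.setdefault(entry["gene_id"], []).append(tm)
    for gid, txs in by_gene.items():
        symbol = gene_meta.get(gid, {}).get("symbol", gid)
        genes[gid] = GeneModel(
            gene_id=gid, symbol=symbol, strand=txs[0].strand, transcripts=txs
        )
    return Annotation(contigs={}, genes=genes, provenance=os.path.abspath(path))


def _new_tx(tid: str) -> dict:
    return {
        "transcript_id": tid,
        "gene_id": None,
        "biotype": "protein_coding",
        "exons": [],
        "cds": [],
        "nf5": False,
        "nf3": False,
    }


def _attr_string(pairs: List[tuple]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(annotation: Annotation, path: str) -> None:
    """Write Ensembl-dialect GTF with one canonical attribute order
    (gene_id, transcript_id, then remaining keys and tags alphabetically)."""
    lines: List[str] = []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        g_start = min(t.exons[0].start for t in gene.transcripts)
        g_end = max(t.exons[-1].end for t in gene.transcripts)
        lines.append(
            "\t".join(
                [
                    gene.contig,
                    "truenull",
                    "gene",
                    str(g_start + 1),
                    str(g_end),
                    ".",
                    gene.strand,
                    ".",
                    _attr_string([("gene_id", gid), ("gene_name", gene.symbol)]),
                ]
            )
        )
        for t in gene.transcripts:
            tags = []
            if t.flag_cds_start_nf:
                tags.append(("tag", "cds_start_NF"))
            if t.flag_cds_end_nf:
                tags.append(("tag", "cds_end_NF"))
            base = [("gene_id", gid), ("transcript_id", t.transcript_id)]
            extra = sorted([("transcript_biotype", t.biotype)] + tags)
            lines.append(
                "\t".join(
                    [
                        t.contig,
                        "truenull",
                        "transcript",
                        str(t.exons[0].start + 1),
                        str(t.exons[-1].end),
                        ".",
                        t.strand,
                        ".",
                        _attr_string(base + extra),
                    ]
                )
            )
            numbered = t.exons if t.strand == "+" else list(reversed(t.exons))
            for i, e in enumerate(numbered, 1):
                lines.append(
                    "\t".join(
                        [
                            e.contig,
                            "truenull",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            _attr_string(base + [("exon_number", str(i))]),
                        ]
                    )
                )
            if t.cds_start_genomic is not None and t.cds_end_genomic is not None:
                for e in numbered:
                    s = max(e.start, t.cds_start_genomic)
                    en = min(e.end, t.cds_end_genomic)
                    if s < en:
                        lines.append(
                            "\t".join(
                                [
                                    e.contig,
                                    "truenull",
                                    "CDS",
                                    str(s + 1),
                                    str(en),
                                    ".",
                                    e.strand,
                                    "0",
                                    _attr_string(base),
                                ]
                            )
                        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
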