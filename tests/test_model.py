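"""Domain model and FASTA/GTF I/O."""

import numpy as np
import pytest

import truenull as tn
from truenull.io import FastaParseError, GtfParseError


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _reference_fasta_parse(text):
    """Independent line-by-line FASTA reader used as an oracle."""
    records, name, chunks = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name, chunks = line[1:].split()[0], []
        elif line.strip():
            chunks.append(line.strip().upper().replace("U", "T"))
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def test_read_fasta_matches_reference_parser(tmp_path):
    text = ">c1\nACGTacgt\nNNAC\n>c2 description here\nuuac\n>c3\nGGGG\n"
    path = tmp_path / "three.fa"
    path.write_text(text)
    contigs = tn.read_fasta(str(path))
    expected = _reference_fasta_parse(text)
    assert [(c.name, c.sequence) for c in contigs.values()] == expected
    assert contigs["c1"].sequence == "ACGTACGTNNAC"  # case + U->T normalization


def test_read_fasta_rejects_bad_characters_with_line(tmp_path):
    path = tmp_path / "bad.fa"
    path.write_text(">c1\nACGT\nAXGT\n")
    with pytest.raises(FastaParseError, match=":3"):
        tn.read_fasta(str(path))


def test_read_fasta_rejects_headerless_file(tmp_path):
    path = tmp_path / "noheader.fa"
    path.write_text("ACGT\n")
    with pytest.raises(FastaParseError):
        tn.read_fasta(str(path))


def test_fasta_write_read_roundtrip(tmp_path, preset):
    path = tmp_path / "out.fa"
    tn.write_fasta(preset.annotation.contigs.values(), str(path))
    back = tn.read_fasta(str(path))
    assert back["chr_rhb"].sequence == preset.contig.sequence
    # 60-column wrapping on write
    lines = path.read_text().splitlines()
    assert max(len(l) for l in lines if not l.startswith(">")) == 60


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

GTF_FIXTURE = """\
chr1\tsrc\tgene\t1\t520\t.\t+\t.\tgene_id "g1"; gene_name "Toy";
chr1\tsrc\ttranscript\t1\t520\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; transcript_biotype "protein_coding"; tag "cds_start_NF";
chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t201\t320\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t401\t520\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t10\t100\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t201\t320\t.\t+\t0\tgene_id "g1"; transcript_id "t1";
"""


def test_read_gtf_fixture_against_adhoc_parse(tmp_path):
    """Exon count, coordinate convention, NF flag and spliced length agree
    with an independent by-hand reading of the fixture."""
    path = tmp_path / "toy.gtf"
    path.write_text(GTF_FIXTURE)
    ann = tn.read_gtf(str(path))
    t = ann.genes["g1"].transcripts[0]
    assert len(t.exons) == 3
    # 1-based inclusive file coords -> 0-based half-open
    assert (t.exons[0].start, t.exons[0].end) == (0, 100)
    assert t.spliced_length == 100 + 120 + 120
    assert t.flag_cds_start_nf and not t.flag_cds_end_nf
    assert (t.cds_start_genomic, t.cds_end_genomic) == (9, 320)
    assert ann.genes["g1"].symbol == "Toy"


GFF3_FIXTURE = """\
##gff-version 3
chr1\tsrc\tgene\t1\t300\t.\t-\t.\tID=g2;Name=Toy2
chr1\tsrc\tmRNA\t1\t300\t.\t-\t.\tID=t2;Parent=g2;tag=cds_end_NF;biotype=protein_coding
chr1\tsrc\texon\t1\t100\t.\t-\t.\tParent=t2
chr1\tsrc\texon\t201\t300\t.\t-\t.\tParent=t2
"""


def test_read_gff3_dialect_nf_tag(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF3_FIXTURE)
    ann = tn.read_gtf(str(path), dialect="gff3")
    t = ann.genes["g2"].transcripts[0]
    assert t.flag_cds_end_nf and not t.flag_cds_start_nf
    assert t.strand == "-" and len(t.exons) == 2


def test_gtf_roundtrip_is_fixed_point(tmp_path, preset):
    """write -> read -> write reaches a fixed point (bit-stable output)."""
    p1, p2, p3 = (tmp_path / f"r{i}.gtf" for i in range(3))
    tn.write_gtf(preset.annotation, str(p1))
    ann2 = tn.read_gtf(str(p1))
    tn.write_gtf(ann2, str(p2))
    ann3 = tn.read_gtf(str(p2))
    tn.write_gtf(ann3, str(p3))
    assert p2.read_bytes() == p3.read_bytes()
    t206 = ann2.genes["GENE_RHB"].transcript("RHB206")
    assert t206.flag_cds_start_nf
    assert len(t206.exons) == 5


def test_read_gtf_cds_without_exons_is_error(tmp_path):
    path = tmp_path / "broken.gtf"
    path.write_text(
        'chr1\tsrc\ttranscript\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        'chr1\tsrc\tCDS\t1\t30\t.\t+\t0\tgene_id "g"; transcript_id "t";\n'
    )
    with pytest.raises(GtfParseError):
        tn.read_gtf(str(path))


# ---------------------------------------------------------------------------
# splicing and coordinate maps
# ---------------------------------------------------------------------------


def test_splice_single_exon_identity_and_minus_strand():
    contig = tn.Contig("c", "AACCGGTTAACC")
    plus = tn.TranscriptModel("tp", "g", "protein_coding",
                              [tn.ExonInterval("c", 2, 8, "+")])
    minus = tn.TranscriptModel("tm", "g", "protein_coding",
                               [tn.ExonInterval("c", 2, 8, "-")])
    assert tn.splice_mrna(plus, {"c": contig}) == "CCGGTT"
    assert tn.splice_mrna(minus, {"c": contig}) == tn.reverse_complement("CCGGTT")


def test_splice_length_conservation_all_preset_isoforms(preset):
    for t in preset.gene.transcripts:
        mrna = tn.splice_mrna(t, preset.annotation.contigs)
        assert len(mrna) == t.spliced_length == sum(e.length for e in t.exons)


def test_splice_oracle_per_exon_extraction(preset):
    """18-exon isoform equals the join of per-exon substring extractions."""
    t = preset.gene.transcript("RHB201")
    seq = preset.contig.sequence
    expected = "".join(seq[e.start : e.end] for e in t.exons)
    assert tn.splice_mrna(t, preset.annotation.contigs) == expected
    assert len(t.exons) == 18


def test_strand_antisymmetry():
    """Splicing a minus-strand transcript equals splicing its mirrored
    plus-strand twin on the reverse-complemented contig."""
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    contig = tn.Contig("c", seq)
    exons = [(20, 70), (110, 160), (200, 260)]
    minus = tn.TranscriptModel(
        "tm", "g", "protein_coding",
        [tn.ExonInterval("c", s, e, "-") for s, e in exons],
    )
    L = len(seq)
    mirror = tn.TranscriptModel(
        "tp", "g", "protein_coding",
        [tn.ExonInterval("c", L - e, L - s, "+") for s, e in reversed(exons)],
    )
    rc_contig = tn.Contig("c", tn.reverse_complement(seq))
    assert tn.splice_mrna(minus, {"c": contig}) == tn.splice_mrna(mirror, {"c": rc_contig})


def test_transcript_coord_roundtrip_and_intronic(preset):
    t = preset.gene.transcript("RHB201")
    rng = np.random.default_rng(0)
    exonic = [
        int(rng.integers(e.start, e.end))
        for e in t.exons
        for _ in range(6)
    ][:100]
    for pos in exonic:
        off = tn.transcript_coord(t, pos)
        assert off is not None
        assert tn.genomic_coord(t, off) == pos
    first_exon = t.exons[0]
    assert tn.transcript_coord(t, first_exon.start) == 0
    intronic = t.exons[0].end + 3  # inside intron 1
    assert tn.transcript_coord(t, intronic) is None


def test_contig_rejects_bad_alphabet_and_empty():
    with pytest.raises(tn.ValidationError):
        tn.Contig("c", "ACGU")
    with pytest.raises(tn.ValidationError):
        tn.Contig("c", "")


def test_transcript_invariants_enforced():
    with pytest.raises(tn.ValidationError):
        tn.TranscriptModel(
            "t", "g", "protein_coding",
            [tn.ExonInterval("c", 10, 50, "+"), tn.ExonInterval("c", 40, 80, "+")],
        )
    with pytest.raises(tn.ValidationError):
        tn.TranscriptModel(
            "t", "g", "protein_coding",
            [tn.ExonInterval("c", 10, 50, "+")],
            cds_start_genomic=60,
        )
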