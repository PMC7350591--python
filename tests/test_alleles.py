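"""Allele engineering: deletions, cassette insertion, Flp/Cre state machine."""

import numpy as np
import pytest

import truenull as tn
from truenull.alleles import EditError, RecombinationError


GENE = "GENE_RHB"


def _surviving_sequences(mutant, tid):
    seq = mutant.contig.sequence
    return [seq[e.start : e.end] for e in mutant.surviving_exons(tid)]


def _original_sequences(preset, tid, indices):
    seq = preset.contig.sequence
    t = preset.gene.transcript(tid)
    return [seq[t.exons[i].start : t.exons[i].end] for i in indices]


# ---------------------------------------------------------------------------
# definitive null
# ---------------------------------------------------------------------------


def test_definitive_null_removes_all_coding_exons(preset):
    m = tn.apply_definitive_null(preset.annotation, GENE)
    # every coding exon gone, including those of the 5'-incomplete isoform
    assert m.surviving_exons("RHB206") == []
    assert m.surviving_exons("RHB207") == []
    surv201 = m.surviving_exons("RHB201")
    assert [e.orig_index for e in surv201] == [0]  # only the 5' UTR exon
    span = preset.gene.exon_union()
    deleted = span[-1].end - span[1].start  # first coding exon .. last exon
    assert m.length_delta == -deleted


def test_definitive_null_single_exon_gene():
    spec = tn.LocusSpec(
        n_exons=1,
        exon_lengths=[90],
        intron_lengths=[],
        isoforms=[tn.IsoformSpec([0], start_exon_codon=(0, 6, "ATG"))],
        seed=1,
        flank=40,
    )
    sim = tn.generate_locus(spec)
    m = tn.apply_definitive_null(sim.annotation, "gene1")
    assert m.surviving_exons(sim.gene.transcripts[0].transcript_id) == []
    assert m.length_delta == -90


# ---------------------------------------------------------------------------
# CRISPR dropout
# ---------------------------------------------------------------------------


def test_dropout_removes_exons_2_3_with_572_delta(preset):
    cut5, cut3 = preset.crispr_dropout_cuts()
    m = tn.apply_crispr_dropout(preset.annotation, GENE, cut5, cut3)
    assert m.removed_exon_indices("RHB201") == [1, 2]
    assert m.length_delta == -572
    assert len(m.contig) == len(preset.contig) - 572


def test_dropout_preserves_surviving_exon_sequences(preset):
    rng = np.random.default_rng(2)
    introns = preset.layout.intron_intervals
    for _ in range(10):
        i5, i3 = sorted(rng.choice(len(introns), size=2, replace=False).tolist())
        cut5 = int(rng.integers(introns[i5][0] + 3, introns[i5][1] - 3))
        cut3 = int(rng.integers(introns[i3][0] + 3, introns[i3][1] - 3))
        m = tn.apply_crispr_dropout(preset.annotation, GENE, cut5, cut3)
        surv_idx = [e.orig_index for e in m.surviving_exons("RHB201")]
        assert _surviving_sequences(m, "RHB201") == _original_sequences(
            preset, "RHB201", surv_idx
        )


def test_dropout_identity_edit_and_exonic_cut_error(preset):
    cut = preset.layout.intron(0)[0] + 10
    m = tn.apply_crispr_dropout(preset.annotation, GENE, cut, cut)
    assert m.length_delta == 0
    assert m.removed_exon_indices("RHB201") == []
    exonic = preset.layout.exon(1)[0] + 5
    with pytest.raises(EditError, match="inside exon"):
        tn.apply_crispr_dropout(preset.annotation, GENE, exonic, exonic + 50)
    # but permitted when explicitly allowed, with the stub kept and flagged
    m2 = tn.apply_crispr_dropout(
        preset.annotation, GENE, exonic, preset.layout.intron(1)[0] + 5,
        allow_exonic_cuts=True,
    )
    stub = m2.exon_map["RHB201"][1]
    assert stub is not None and stub.truncated


def test_dropout_with_scar(preset):
    cut5, cut3 = preset.crispr_dropout_cuts()
    m = tn.apply_crispr_dropout(preset.annotation, GENE, cut5, cut3, scar="TTTT")
    assert m.length_delta == -572 + 4
    assert len(m.contig) == len(preset.contig) - 568


# ---------------------------------------------------------------------------
# KO-first series
# ---------------------------------------------------------------------------


@pytest.fixture()
def tm1a(preset):
    return tn.apply_design(preset.annotation, GENE, tn.rhbdf1_design(preset, "tm1a"))


def test_tm1a_residual_elements(tm1a):
    names = [e.name for e in tm1a.residual_elements]
    assert {"En2_SA", "lacZ", "neo", "SV40_pA"} <= set(names)
    assert names.count("FRT") == 2
    assert names.count("loxP") == 3  # KOMP topology: two in-cassette + one downstream
    sa = tm1a.elements_named("En2_SA")[0]
    assert sa.end - sa.start == 115
    # no exon removed by insertion alone; exon sequences intact
    assert tm1a.removed_exon_indices("RHB201") == []


def test_tm1a_exon_sequences_unchanged(preset, tm1a):
    surv_idx = [e.orig_index for e in tm1a.surviving_exons("RHB201")]
    assert _surviving_sequences(tm1a, "RHB201") == _original_sequences(
        preset, "RHB201", surv_idx
    )


def test_cre_on_tm1a_gives_tm1b(preset, tm1a):
    tm1b = tn.cre_recombine(tm1a)
    assert tm1b.kind == "tm1b"
    assert tm1b.removed_exon_indices("RHB201") == list(range(3, 11))  # exons 4-11
    names = [e.name for e in tm1b.residual_elements]
    assert "En2_SA" in names and "lacZ" in names and "SV40_pA" in names
    assert "neo" not in names
    assert names.count("loxP") == 1  # one recognition site of the pair remains


def test_flp_on_tm1a_gives_tm1c_conditional_ready(preset, tm1a):
    tm1c = tn.flp_recombine(tm1a)
    assert tm1c.kind == "tm1c"
    # cassette gone, one FRT scar, loxP pair intact, all exons restored
    names = [e.name for e in tm1c.residual_elements]
    assert names.count("FRT") == 1 and names.count("loxP") == 2
    assert set(names) == {"FRT", "loxP"}
    assert tm1c.removed_exon_indices("RHB201") == []
    surv_idx = [e.orig_index for e in tm1c.surviving_exons("RHB201")]
    assert _surviving_sequences(tm1c, "RHB201") == _original_sequences(
        preset, "RHB201", surv_idx
    )


def test_state_machine_flp_then_cre_is_tm1d(tm1a):
    tm1d = tn.cre_recombine(tn.flp_recombine(tm1a))
    assert tm1d.kind == "tm1d"
    assert tm1d.removed_exon_indices("RHB201") == list(range(3, 11))
    assert [e.name for e in tm1d.residual_elements] == ["FRT", "loxP"]


def test_state_machine_illegal_transitions(tm1a):
    tm1b = tn.cre_recombine(tm1a)
    with pytest.raises(RecombinationError):
        tn.cre_recombine(tm1b)  # cre twice: no loxP pair left
    with pytest.raises(RecombinationError):
        tn.flp_recombine(tm1b)
    tm1d = tn.cre_recombine(tn.flp_recombine(tm1a))
    with pytest.raises(RecombinationError):
        tn.flp_recombine(tm1d)


def test_tm1a_floxed_range_must_be_downstream(preset):
    design = tn.AlleleDesign(
        "tm1a",
        floxed_exons=(1, 2),
        cassette=tn.default_cassette(insertion_intron=5),
    )
    with pytest.raises(EditError, match="downstream"):
        tn.apply_design(preset.annotation, GENE, design)


def test_edit_log_delta_conservation_random_designs(preset):
    """Sum of edit-log deltas equals the observed contig length change for
    arbitrary designs, including composed recombination trajectories."""
    rng = np.random.default_rng(7)
    original_len = len(preset.contig)
    for _ in range(12):
        kind = ["definitive_null", "crispr_dropout", "tm1a", "tm1b", "tm1c", "tm1d"][
            int(rng.integers(0, 6))
        ]
        if kind == "crispr_dropout":
            introns = preset.layout.intron_intervals
            i5, i3 = sorted(rng.choice(len(introns), size=2, replace=False).tolist())
            design = tn.AlleleDesign(
                "crispr_dropout",
                deleted_interval=(
                    int(rng.integers(*introns[i5])),
                    int(rng.integers(*introns[i3])),
                ),
            )
        else:
            design = tn.rhbdf1_design(preset, kind, cassette_seed=int(rng.integers(100)))
        m = tn.apply_design(preset.annotation, GENE, design)
        assert m.length_delta == len(m.contig) - original_len


def test_write_mutant_serialization(tmp_path, preset):
    m = tn.apply_design(preset.annotation, GENE, tn.rhbdf1_design(preset, "tm1b"))
    prefix = str(tmp_path / "tm1b")
    tn.write_mutant(m, prefix)
    back = tn.read_fasta(f"{prefix}.fa")
    assert back["chr_rhb"].sequence == m.contig.sequence
    ann = tn.read_gtf(f"{prefix}.gtf")
    assert "GENE_RHB" in ann.genes
    import json

    log = json.loads((tmp_path / "tm1b_edits.json").read_text())
    assert log["allele_kind"] == "tm1b"
    assert log["length_delta"] == m.length_delta
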