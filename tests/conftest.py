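import pytest

import truenull as tn


@pytest.fixture(scope="session")
def preset():
    """The packaged 18-exon multi-isoform locus, one build per session."""
    return tn.rhbdf1_like_preset(seed=11)


@pytest.fixture(scope="session")
def genotyping_primers(preset):
    seq = preset.contig.sequence
    (fs, fe), (rs, re_) = preset.genotyping_primer_sites()
    return tn.PrimerPair(seq[fs:fe], tn.reverse_complement(seq[rs:re_]))


@pytest.fixture(scope="session")
def rtpcr_primers(preset):
    seq = preset.contig.sequence
    (fs, fe), (rs, re_) = preset.rtpcr_primer_sites()
    return tn.PrimerPair(seq[fs:fe], tn.reverse_complement(seq[rs:re_]), "cdna")
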