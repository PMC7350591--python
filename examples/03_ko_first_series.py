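"""The KO-first allele series: tm1a and its Flp/Cre derivatives.

tm1a inserts a promoter-trap cassette (FRT / En2 splice acceptor / lacZ /
SV40 pA / loxP / neo / FRT / loxP) into intron 3 and floxes exons 4-11.
Cre yields tm1b (null-intent); Flp yields tm1c (conditional-ready); Flp
then Cre yields tm1d. RT-PCR across the deletion reveals whether the
retained splice acceptor is captured into the mutant mRNA.
"""

import truenull as tn

locus = tn.rhbdf1_like_preset(seed=1)
seq = locus.contig.sequence

tm1a = tn.apply_design(locus.annotation, "GENE_RHB", tn.rhbdf1_design(locus, "tm1a"))
tm1b = tn.cre_recombine(tm1a)
tm1c = tn.flp_recombine(tm1a)
tm1d = tn.cre_recombine(tm1c)
for m in (tm1a, tm1b, tm1c, tm1d):
    names = [e.name for e in m.residual_elements]
    removed = [i + 1 for i in m.removed_exon_indices("RHB201")]
    print(f"{m.kind}: residual {names}; exons removed {removed or 'none'}")

(fs, fe), (rs, re_) = locus.rtpcr_primer_sites()
primers = tn.PrimerPair(seq[fs:fe], tn.reverse_complement(seq[rs:re_]), "cdna")
transcripts = tn.enumerate_mutant_transcripts(tm1b)
for mt in transcripts:
    print(f"tm1b transcript {mt.variant_id}: {len(mt.mrna)} nt, "
          f"RT-PCR {tn.insilico_pcr(mt.mrna, primers).products}")

# The exon3-exon12 join gives a 209-nt product; the variant that retains
# the 115-nt En2 splice-acceptor fragment gives 324 nt instead -- the
# size shift that exposes cassette sequence inside the mutant mRNA.
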