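"""CRISPR dropout of the start-codon exons, validated by in-silico PCR.

Two intronic cuts excise exons 2-3 (the exons carrying the canonical start
codon) as a 572-nt genomic dropout. A genotyping primer pair spanning the
region sizes the alleles exactly as a gel would.
"""

import truenull as tn

locus = tn.rhbdf1_like_preset(seed=1)
seq = locus.contig.sequence

(fs, fe), (rs, re_) = locus.genotyping_primer_sites()
primers = tn.PrimerPair(seq[fs:fe], tn.reverse_complement(seq[rs:re_]))

cut5, cut3 = locus.crispr_dropout_cuts()
mutant = tn.apply_crispr_dropout(locus.annotation, "GENE_RHB", cut5, cut3)

print(f"deletion size: {cut3 - cut5} nt")
print(f"edit-log length delta: {mutant.length_delta:+d} nt")
print(f"exons removed from the full-length isoform: "
      f"{[i + 1 for i in mutant.removed_exon_indices('RHB201')]}")
print(f"wildtype band: {tn.insilico_pcr(locus.contig, primers).products} nt")
print(f"mutant band:   {tn.insilico_pcr(mutant.contig, primers).products} nt")

# A 1300-nt wildtype product shrinking to a single 728-nt product is the
# size signature of a clean 572-nt dropout between the primer sites.
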