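"""Build the packaged multi-isoform locus and inspect its annotation.

The locus mimics a gene whose isoform repertoire defeats naive knockout
logic: a full-length AUG-start isoform, a short 5'-incomplete isoform
(cds_start_NF) covering only the last five exons, and a non-AUG (CGC)
start isoform.
"""

import truenull as tn

locus = tn.rhbdf1_like_preset(seed=1)

print(f"contig: {locus.contig.name}, {len(locus.contig)} nt, 18 exons")
for t in locus.gene.transcripts:
    flags = " cds_start_NF" if t.flag_cds_start_nf else ""
    print(f"  {t.transcript_id}: {len(t.exons)} exons, "
          f"spliced {t.spliced_length} nt{flags}")

seq = locus.contig.sequence
for name, pos in locus.landmarks.items():
    print(f"  landmark {name}: position {pos}, codon {seq[pos:pos + 3]}")

# The canonical start sits in exon 2; the exon-4 AUG is in the same reading
# frame, so a deletion of exons 2-3 leaves a template for an N-terminally
# truncated protein. The 5'-incomplete isoform has no start codon at all --
# the annotation asserts its CDS is truncated at the 5' end.
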