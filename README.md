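# truenull

**Is your knockout really a null?** `truenull` is a Python library for
triaging mouse gene-targeting designs — definitive-null deletions, CRISPR
exon dropouts, and KO-first (tm1a/tm1b/tm1c/tm1d) conditional alleles — for
the ways an "inactivated" gene can keep making protein:

* **exon skipping / deletion-joined splicing** — flanking exons splice
  across the deleted block, and a downstream in-frame AUG (or a
  near-cognate/non-AUG codon such as CGC) reinitiates translation of an
  N-terminally truncated protein;
* **splice-acceptor retention** — the En2 splice acceptor of a residual
  KO-first cassette is captured into the mutant mRNA, adding an in-frame
  stop and a short truncated product;
* **incomplete-CDS isoforms** — transcripts annotated `cds_start_NF` /
  `cds_end_NF` (5′/3′-incomplete CDS) that the targeting event never
  touches and that are poor NMD substrates.

The pipeline applies a design to a locus, enumerates the candidate mutant
mRNAs, scans them for translation starts, classifies each product under the
classical NMD exon-junction rule (a stop > 50 nt upstream of the last
exon–exon junction is a decay target; stops in the last exon escape), and
rolls the evidence into a per-gene call: `TRUE_NULL_LIKELY` or
`ESCAPE_PRONE`. Around the core sit an in-silico PCR engine for allele
validation, a gene-level incomplete-CDS census, and a census of strains
whose tm1a and tm1b alleles were assigned conflicting viability classes.

Because real targeting data cannot ship with the package, a synthetic-data
module builds annotations with exactly planted structure, including an
18-exon preset locus whose isoform repertoire (full-length AUG isoform,
5′-incomplete exons-14–18 isoform, CGC-start isoform, in-frame exon-4 AUG,
alternative first exon 199 bp upstream) reproduces the published geometry
of a gene that defeated three different knockout strategies.

## Worked example

```python
import truenull as tn

locus = tn.rhbdf1_like_preset(seed=1)
seq = locus.contig.sequence

# genotyping PCR across the start-codon exons
(fs, fe), (rs, re_) = locus.genotyping_primer_sites()
primers = tn.PrimerPair(seq[fs:fe], tn.reverse_complement(seq[rs:re_]))
print(tn.insilico_pcr(locus.contig, primers).products)       # [1300]

# CRISPR dropout of exons 2-3 (the 572-nt start-codon deletion)
cut5, cut3 = locus.crispr_dropout_cuts()
mutant = tn.apply_crispr_dropout(locus.annotation, "GENE_RHB", cut5, cut3)
print(tn.insilico_pcr(mutant.contig, primers).products)      # [728]

# screen the allele for residual-product escape
_, _, report = tn.run_screen(
    locus.annotation, "GENE_RHB", tn.rhbdf1_design(locus, "crispr_dropout")
)
print(report.classification)                                  # ESCAPE_PRONE
print(sorted(report.evidence_types()))   # ['NF_UNTOUCHED', 'REINIT_ORF']
```

The wildtype 1300-nt band shrinking to a single 728-nt band is the size
signature of a clean 572-nt dropout; the screen still calls the allele
escape-prone, because the deletion-joined transcript reinitiates at an
in-frame AUG in exon 4 (an ORF of 660 codons whose stop lies in the last
exon, hence NMD-escaping) and because the 5′-incomplete exons-14–18
isoform is untouched. The same screen on the definitive-null design
returns `TRUE_NULL_LIKELY` with no evidence, and on the tm1b allele
returns `ESCAPE_PRONE` with both untouched-NF and splice-acceptor-retention
evidence (RT-PCR across the deletion: 324 nt instead of the 209-nt clean
join, the 115-nt retained acceptor fragment in between).

The `examples/` directory has one short script per capability; each prints
the numbers above and says what they mean. A thin CLI mirrors the library
(`truenull simulate|apply-allele|predict-transcripts|scan-orfs|nmd|census|screen|pcr|conflicts`);
`truenull census --gtf <your.gtf>` and the `--fasta/--gtf` options of
`screen` run the same operations on a user-supplied Ensembl-style
annotation.

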