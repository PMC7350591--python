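# Methods

## The problem being modelled

A gene-targeting design is meant to produce a null allele, but the edited
locus can keep templating protein. Three mechanisms are modelled here:

1. **Deletion-joined transcripts with translation reinitiation.** When the
   exons carrying the start codon are removed, the flanking exons splice
   together and ribosomes can initiate at the next suitable codon —
   canonically a downstream in-frame AUG, but near-cognate codons (CTG,
   GTG, ACG, ATT, ATA, ATC) and CGC, which some natural 5′-incomplete
   isoforms use, are supported behind `StartPolicy.extended()`.
2. **Splice-acceptor retention.** The KO-first cassette carries an En2
   splice acceptor; after Cre conversion a residual SA fragment can be
   captured between the surviving exons, adding an in-frame stop (TAA) and
   yielding a short truncated product.
3. **Untouched incomplete-CDS isoforms.** Transcripts flagged
   `cds_start_NF` / `cds_end_NF` in Ensembl-style annotation lack an
   asserted start/stop codon; when a targeting event does not intersect
   them they persist, and their geometry makes them poor NMD substrates.

The per-gene screen collects these three evidence classes and calls the
design `ESCAPE_PRONE` iff any evidence exists, else `TRUE_NULL_LIKELY`.

## Coordinates and formats

Internal coordinates are 0-based half-open; GTF I/O converts to/from the
1-based inclusive convention at the boundary. FASTA goes through Biopython
(wrapped at 60 columns on write, case-normalised and U→T on read); GTF and
GFF3 are parsed with gffutils; the NF flags come from Ensembl `tag`
attributes, with `mRNA_start_NF` accepted as a GFF3-era synonym. The GTF
writer emits one canonical attribute order (gene_id, transcript_id, then
remaining keys alphabetically) so that outputs are bit-stable; a
write→read→write cycle is a fixed point. N bases are legal in sequence;
any codon containing N translates to X and never matches a start or stop.

## The synthetic-data generators

Generators plant structure exactly — counts are `round(n × fraction)`,
never Bernoulli draws — so the downstream census and conflict operations
recover the planted parameters with zero sampling noise, and every
asserted start codon verifiably occurs at its stated offset.

Three hygiene conventions make the scan results interpretable:

* all exon, intron and flank sequence is generated AUG-free, so the only
  initiation sites a scanner finds are the planted ones;
* the first and last base of every exon-like segment is fixed to `C`,
  which occurs in no start or stop triplet, so no ATG/TAA/TAG/TGA can ever
  span a splice junction regardless of which segments are joined;
* introns begin `GT` and end `AG`.

**The preset locus** is an 18-exon, plus-strand, single-contig gene with
three isoforms: a full-length transcript with its AUG at exon-2 offset 31;
a 5′-incomplete (`cds_start_NF`) transcript comprising only exons 14–18;
and a CGC-start transcript over exons 13–18. Exon 4 carries an AUG at
offset 60, in frame with the canonical start; an alternative-first-exon
window (100 nt) sits 199 bp upstream of exon 1. Exon and intron lengths
are arbitrary (they are *not* the real lengths of any gene) but were
chosen so that three published size relationships hold exactly: the
intron-1/intron-3 cut pair measures 572 nt and wholly contains exons 2–3;
the packaged genotyping primers give 1300 nt on wildtype and 728 nt after
the dropout; and the exon-3/exon-12 RT-PCR primers give 209 nt on the
clean exon join versus 324 nt with the 115-nt SA fragment retained.
Exons 4–11 sum to 1100 nt (≠ 0 mod 3) on purpose: the post-Cre
exon3→exon12 join is frameshifted, so the canonical start terminates early
on that transcript, while the retention transcript reads in frame into the
SA stop. The canonical reading frame is cleared of stop codons from the
start through the planted TAA at exon-18 offset 250, which simultaneously
clears the frames of the exon-4 reinitiation ORF, the CGC ORF and the NF
isoform (they share codon boundaries by construction). Two seeds give
byte-different background sequence but identical architecture.

What the generators deliberately do **not** emulate: realistic base
composition or repeats, splice-site strength, isoform abundance, or
sequencing reads. Green tests on synthetic loci therefore demonstrate the
correctness of the *logic* (coordinate arithmetic, splicing, scanning,
classification), not performance on real genomes — real-annotation runs go
through the same `census`/`screen` entry points with a user-supplied
GTF/FASTA.

## Allele engineering

The KO-first cassette uses the KOMP-CSD topology
`FRT–En2_SA–lacZ–SV40_pA–loxP–neo–FRT–loxP … [floxed exons] … loxP`
(three loxP sites), which is the unique minimal layout under which the
required state machine holds: Flp on tm1a excises the FRT-bracketed block
(→ tm1c, one FRT scar, loxP pair intact), Cre on tm1a excises between the
outermost loxP sites (→ tm1b, neo and floxed exons gone, SA–lacZ–pA
retained), Cre on tm1c → tm1d. All other transitions raise. Cassette
component sequences are synthetic placeholders of configurable length
(defaults: SA 115 nt with its TAA at offset 51, lacZ 300, neo 250, pA 60)
with real 34-nt FRT and loxP recognition sequences; the SA stop offset is
divisible by 3 so a capture that enters the fragment on a codon boundary
hits it in frame.

CRISPR dropout joins the cut ends with no scar by default (an optional
scar string is supported). Exons wholly inside a deletion are removed from
every isoform model; a deletion that truncates an exon keeps the stub and
flags it `truncated` (cuts inside exons are rejected unless
`allow_exonic_cuts` is set). The definitive null deletes from the first to
the last coding exon over all isoforms. Every edit appends a log record
whose deltas sum to the observed contig-length change; surviving exon
sequences are byte-identical to the originals.

## Transcript enumeration

Rule-based and exhaustive within four event classes (deletion-join, SA
retention, pA truncation for tm1a loci, alternative first exon), with no
probabilistic weighting: the outputs are candidates for ORF/NMD triage.
A deletion-joined transcript requires surviving exons on **both** sides of
the removed block — which is why a definitive null (nothing coding
survives downstream) yields an empty list. SA retention splices the
fragment between the nearest surviving upstream and downstream exons, the
only topology with experimental support. The alternative first exon is a
fixed-length window (default 100 nt at offset 199, both configurable)
substituting for the gene's conventional exon 1; published data locate its
position, not its length. Untouched NF-flagged isoforms are emitted
unchanged. Output is deduplicated by exact mRNA sequence with
deterministic priority (join < retention < truncation < alt-exon <
untouched) and capped at `max_variants`.

## ORF scanning, translation, mass

The scanner reports **all** candidate starts (leaky-scanning view): every
occurrence of every policy codon opens a frame that runs to the first
in-frame stop. ORFs without a stop are flagged `no_stop`; ORFs shorter
than `min_orf_codons` (default 50, the "plausibly functional truncation"
threshold — a judgment call, configurable and always reported rather than
silently filtered) are flagged `short_orf`. Non-AUG initiators are decoded
as initiator methionine, matching initiator-tRNA biology. Product masses
are average (not monoisotopic) residue masses via Biopython, reported in
kDa — the convention that matches SDS-PAGE-style size estimates;
monoisotopic mass is available behind a separate function.

## NMD rule and screen

The classical 50-nt exon-junction rule is the default
(`junction_rule_nt` configurable 0–100): a stop more than the threshold
upstream of the last junction → `NMD_TARGET`; in the last exon, within the
window, or on a single-exon transcript → `ESCAPE`; no stop → `NO_STOP`.
The distance convention is `last_junction − stop_codon_offset` (negative
when the stop is downstream).

One deliberate asymmetry: ORFs terminating **inside a retained SA
fragment** are reported as `SA_RETENTION_PRODUCT` evidence regardless of
their junction-rule verdict, with the verdict recorded alongside. Such
stops sit far upstream of the remaining junctions and classify as decay
targets, yet retention products have been observed at the protein level —
the screen surfaces both facts instead of letting the rule suppress the
observation.

The incomplete-CDS census lifts transcript-level NF flags to gene level (a
gene counts once however many NF transcripts it has), filters to
protein-coding biotype, and reports nearest-integer percentages — the
rounding style used in published gene-level censuses. "At least"-style
published claims map to ≥ comparisons and are never inflated.

## In-silico PCR and the conflict census

Primer binding is exact-match only (the modelled assays are presence/size
assays; mismatch tolerance would add nothing testable) and product length
is inclusive of both primers, the standard gel-size convention. All
forward×reverse site pairings with the forward site 5′ of the reverse site
and span ≤ `max_product` (default 10 kb) are reported, sorted ascending.

The conflict census marks a gene discordant when it has two or more allele
records (tm1a/tm1b/em-series) of unequal viability class; the percentage
denominator defaults to the number of genes in the table but accepts the
full-cohort size when the table lists only the discordant rows. The
packaged 17-gene table preserves the published gene symbols and allele
labels; because the flattened source table does not preserve its column
layout, class assignments are reconstructed (the three genes described in
prose carry their stated classes; the rest are assigned discordant pairs),
which is sufficient because the census consumes only class inequality.

## Numerical and degenerate-input choices

Deterministic throughout: every generator takes a seed, enumeration and
evidence collection have fixed tie-breaks (event priority, then source
isoform order), and repeated runs are byte-identical. Degenerate inputs
are defined rather than undefined: `cut5 == cut3` is an identity edit with
a zero-delta log record; an empty amplicon list is "no band", not an
error; an annotation with no protein-coding genes makes the census raise.

## Known limitations

* No splice-site strength or Kozak-context model: enumeration and scanning
  are exhaustive, so real loci will produce candidates that are never
  expressed; the screen is a sensitivity-first triage, and `ESCAPE_PRONE`
  means "warrants transcript-level validation", not "escapes".
* The NMD rule is the 50-nt heuristic, not a quantitative efficiency
  model.
* Quantities that depend on real gene sequence — genome-wide census
  percentages for real annotations, and the specific product sizes/masses
  of real truncated proteins — are outside the packaged runs; they require
  a user-supplied Ensembl GTF/FASTA (release-dependent) through the same
  census/screen entry points.
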