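# Methods

This note documents the models, algorithms and design choices behind the
`retrocopy` package: what each stage assumes, which knobs matter, what
the simulator does and does not emulate, and the numerical conventions
that keep the stages consistent with one another.

## The biological model

A processed pseudogene (retrocopy) is created when the LINE-1
endonuclease/reverse-transcriptase machinery acts on a mature mRNA. The
machinery nicks genomic DNA at a `TTTT|AA` consensus (or a similar
T/A-rich site), primes reverse transcription from the transcript's polyA
tail, and integrates a cDNA copy. The resulting DNA lesion has a
characteristic anatomy that every stage of this package keys on:

- **spliced structure** — the insert contains exon sequence only, so in
  DNA reads the exon–exon boundaries look like canonical splice
  junctions, observable in DNA only because the introns are gone;
- **polyA tail** at the 3′ end, joined between the TTTT and the AA of
  the motif;
- **target-site duplication (TSD)** of typically 8–20 bp, created by the
  staggered nicks — the reference segment between the two breakpoints
  appears on both sides of the insert; occasionally the nicks resolve
  with a **target-site deletion** instead, or a blunt join;
- **5′ truncation** — reverse transcription frequently aborts, so most
  events lack the 5′ end of the transcript;
- **twin-priming inversion** — when the second nicked strand also primes
  cDNA synthesis internally, the insert consists of two segments of the
  cDNA in opposite orientations that partition it without duplicated
  template, joined with 1–4 bp microhomology, and with 1–3 bp
  microhomology at the 5′ insertion point.

## Coordinates and data model

All in-memory coordinates are 0-based, half-open; GTF and SAM readers
convert at the boundary. Exon indices are 1-based in transcription
direction (exon 1 is 5′-most on the coding strand), matching catalogue
usage such as "exons 11–14; 44". An insertion site is held as two
reference coordinates: `a`, where the left flank ends, and `b`, where
the right flank resumes; `a > b` is a TSD of length `a − b` (the segment
`[b, a)` is duplicated), `a < b` a target-site deletion, `a = b` a blunt
join. The junction adjoining the insert's 5′ end is `a` for a
plus-orientation insert and `b` for minus; the polyA junction is the
other one.

## Detection: genome mode

Input is read pairs aligned to the transcriptome and projected back to
genome space. Projection expands alignments across exon boundaries with
`N` operations (one "split" per intron crossed) and flips the strand for
minus-strand transcripts; pairs from retrocopy DNA acquire a large
genome-space insert size because their mates bracket introns that are
absent from the template DNA. Default thresholds (all configurable, used
verbatim from the published pipeline): insert size within [300 bp,
50 kb]; at most 2 CIGAR splits per mate; first and last match blocks
≥ 10 bp; MAPQ ≥ 10. Pairs whose four coordinates (both mates' start and
end) fall inside a single protein-coding gene footprint are counted per
gene; candidates need ≥ 4 tumour pairs ("more than three") and zero
matched-normal plus panel pairs. Candidates representing < 3 exons or
< 2 observed canonical splice junctions are demoted to low confidence
rather than dropped. The published pipeline's final manual IGV review is
replaced by machine-readable per-candidate evidence (supporting pair
lists and per-filter attrition counts).

Two-sided filtering has a consequence worth knowing: the insert-size
window binds the tumour *and* the normal/panel counts, so the candidate
set is monotone only under relaxation of the quality thresholds (MAPQ,
splits, terminal match). Widening the insert window below the
concordant-fragment size floods the normal counts and can veto true
candidates. The 300 bp floor therefore presumes a sequencing library
whose fragment-size distribution lies essentially entirely below 300 bp.

## Detection: exome mode

Exome capture covers exons only, so the footprint of a retrocopy is a
set of properly oriented (FR) pairs whose inner span fully contains one
or more annotated introns — apparent deletions. Pairs are clustered by
(gene, skipped-intron set), which absorbs breakpoint scatter without a
coordinate tolerance parameter; retained clusters must span ≥ 500 bp and
< 50 kb (the size range covering most human introns). A gene with ≥ 2
retained clusters jointly involving ≥ 3 exons is a candidate. Exclusion:
any normal/panel pair supporting the same skipped-intron configuration,
or a skipped intron with ≥ 80 % reciprocal overlap (configurable; no
published criterion exists) against user-supplied germline-deletion
intervals in BED — a stand-in for a germline structural-variant database.
Omitting the BED skips that step with a prominent warning. The full
published structural-variant caller behind the exome analysis is
external; this clustering is a documented simplification that reproduces
its behaviour on intron-skip signatures.

## Insertion-site mapping

For each candidate, pairs with one mate in the source gene's exons and
the other mapped elsewhere (MAPQ ≥ 10) are collected as links; link
mates are clustered (gap ≤ 3 kb, chosen to span the largest simulated
target-site deletions plus fragment scatter) and the largest cluster,
padded by 300 bp (≈ fragment mean + 4 s.d.), defines the search window.
Soft-clipped reads anchored in the window are validated by realigning
the clip with an internal exact-seed (13 bp) and-extend aligner — a
BLAT replacement that removes the external-tool dependency at this
scale — allowing ≤ 1 mismatch per 20 bp of extension and rejecting
ambiguous (multi-hit) placements. Suffix-clip anchor ends vote for `a`,
prefix-clip anchor starts vote for `b`; modal values win.

Insert orientation is inferred in priority order: (1) a polyA/polyT
homopolymer clip (the tail's strand is unambiguous); (2) which side's
clip realigns to the extreme 3′ end of the cDNA — this rule stays valid
for twin-priming inversions, where raw clip-hit strands are misleading
because the insert's 5′ part is itself reverse-complemented; (3) majority
of clip-hit strands. PolyA length is the longest junction-anchored run
with ≥ 90 % A content, no two consecutive non-A bases, and ≥ 10 bp
(the published account gives no threshold; it reports one tail of
"at least 50 bp"). The motif test is deliberately fuzzy ("TTTTAA or very
similar"): ≥ 3 T immediately 5′ and ≥ 1 A immediately 3′ of the break on
the insertion strand, with the exact-consensus state reported separately.

Twin-priming inversions are detected from reads anchored inside the
source gene whose clips realign to the cDNA in the orientation opposite
to the gene strand (a comparison that is invariant to read direction).
The junction-adjacent transcript coordinates of the two sides are the
truncation point and the internal breakpoint `k`; evidence segments must
partition the cDNA suffix at `k` — any segment straddling `k` would mean
duplicated template and flags the call. Junction microhomologies are
computed as the maximal overlap (suffix of left = prefix of right).
Events without confidently mapped links (e.g. insertions into repetitive
sequence, modelled as MAPQ-0 link mates) are reported unmapped with a
reason; one-sided resolutions are reported as partial junctions, with
the catalogue recording which side mapped.

The expressed-junction resolver mirrors the DNA mapper for RNA reads:
reads mapping contiguously to a known transcript are consumed; the rest
are shattered into 13-mers, placed at unique genome positions (either
strand), extended one base at a time while the exact match holds, and
merged along diagonals; adjacent fragments on different loci define the
expressed breakpoint.

## Catalogue statistics and enrichment test

Sample identifiers sharing the stem before trailing lowercase letters
(e.g. PD7354c/h/k/r) collapse to one patient; cell lines are their own
category. The truncation and inversion fractions use all events as
denominator; the TSD and polyA fractions use only fully mapped sites —
rows whose TSD field is a length or "None"; "NA" means the site was
unmapped or unresolved and is a distinct state. Insertion contexts
(intron *i*, exon, 3′ UTR, upstream/5′ UTR, intergenic, at-rearrangement)
are counted among mapped events; a point inside two overlapping genes
yields a context per gene, with orientation reported relative to each
host.

The enrichment test asks whether retrocopy template genes are highly
expressed in the matching tissue: the fraction of template genes at or
above the cohort's 75th percentile (a gene exactly at the threshold
counts as top-quartile) and a two-sided Wilcoxon rank-sum test of
template genes against all remaining genes — exact enumeration of the
rank-sum distribution when the template set has ≤ 25 genes, normal
approximation otherwise. Published cohort expression references are
external, so the test requires a user-supplied expression table and no
attempt is made to reproduce published enrichment values on real data.

## The simulator

The generator is the package's study-conditions definition, not a test
fixture. Defaults: 2 chromosomes × 150 kb of uniform random sequence;
12 genes of 4–8 exons (150–400 bp) and introns of 500–3000 bp, random
strand, CDS bounds leaving short UTRs; TTTTAA/TTAAAA motifs planted in
intergenic space at one per 2 kb on top of chance occurrences. Eight
retrocopy events are drawn from distinct source genes with the observed
catalogue feature rates as probabilities: 5′ truncation 0.74 (uniform
truncation point constrained to leave ≥ 3 exons and ≥ 2 junctions; a
3′-biased geometric alternative is available since no distribution is
published), twin-priming inversion 0.21 (breakpoint away from splice
boundaries, redrawn until the internal junction shows 1–4 bp
microhomology and the 5′ insertion point 1–3 bp), polyA presence 0.88
with length uniform in 30–80 bp (one published tail is "at least
50 bp"; no distribution is given), site class TSD 0.67 (length 8–20 bp,
configurable down to 5 bp to reflect catalogue outliers) / target-site
deletion 0.21 (100–2000 bp; an 8 kb case is exercised separately in
tests) / blunt otherwise, and motif-biased site choice 0.9 with the
polyA end joined between TTTT and AA on the insertion strand.

Reads: 100 bp paired ends at 30× tumour and matched-normal coverage and
a 2-sample × 5× unmatched panel (the real panel was 23 low-depth
genomes; the package takes the panel as input and records its size).
Fragment lengths are normal (mean 220 bp, s.d. 20) hard-truncated at
± 3.5 s.d. — a tightly size-selected library whose upper tail lies below
the 300 bp detection floor. This is a modelling commitment, not a
convenience: with appreciable fragment mass above 300 bp the published
insert filter could not separate retrocopy pairs from concordant pairs.
A uniform substitution-error rate (default 0.001) is applied; there is
no quality-score model, no indel errors, no coverage bias, and no
somatic SNV/CNV background.

Because every inserted base has known provenance, the simulator computes
each read's alignment to the *original* reference itself via a segment
map (tumour interval → reference/transcript interval + strand): reads
crossing junctions are emitted with soft-clips anchored on the larger
side, reads wholly inside the retrocopy map to the source locus (genome
space) or the transcript (transcriptome space), polyA-only reads are
unmapped. Insertion sites where a chance base match would let an aligner
extend past the true junction (insert's first base equal to the
reference base after `a`, or last base equal to the base before `b`) are
redrawn, making the constructed coordinates the unique
maximal-alignment representation — soft-clip positions, the detection
stack and the haplotype-diff oracle then agree exactly, with no
left-alignment convention needed. Everything is driven by a single
seeded generator; identical configurations produce byte-identical
outputs.

What passing tests on these data do **not** show: performance under real
aligner artefacts (multi-mapping in repeats, chimeric mis-alignments),
GC or capture bias, contamination, subclonality, or genomes with
realistic repeat content. The zero-false-positive results in particular
reflect the clean background; on real data the normal-panel and
germline-deletion filters carry that burden.

## Orchestration and reproducibility

`run_end_to_end` chains simulate → project → genome-mode detection →
insertion mapping → exome-mode detection on capture-restricted reads →
annotation → summary, and writes a recovery report comparing calls with
truth (event recall, breakpoint/TSD exactness, polyA and inversion
detection, no-duplication violations) plus a run manifest (version,
config hash, input checksums, seed, per-stage counts) referenced from
every output table. Default problem sizes (300 kb genome, 8 events, 30×)
complete the whole pipeline in well under a minute on one CPU; they are
the package's chosen desk-scale study conditions, and the acceptance
script runs them unchanged.

## Known limitations

- Genome mode requires transcriptome-space alignments as input; it does
  not realign reads.
- Multi-transcript genes are projected per transcript and resolved at
  the gene level; how the published pipeline collapsed transcripts
  before split counting is not stated, and the per-transcript choice is
  logged.
- Insertions at genomic rearrangement breakpoints are passed through
  unclassified (breakpoints on different chromosomes), not modelled.
- The exome clustering is a simplified stand-in for a general
  structural-variant caller and only sees intron-skip signatures.
- Non-templated junction bases are reported as untemplated sequence
  without further modelling.
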