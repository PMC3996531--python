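# retrocopy

Detection and characterisation of **somatically acquired processed
pseudogenes (retrocopies)** in paired tumour/normal sequencing data.

A processed pseudogene is a cDNA copy of a mature mRNA — introns spliced
out, polyA tail retained — written back into the genome by the LINE-1
retrotransposition machinery acting in *trans*. In cancer genomes these
events arise somatically, carrying the classic structural signature of
L1 endonuclease/reverse-transcriptase activity: an 8–20 bp target-site
duplication (TSD) or occasionally a target-site deletion, a polyA tail
joined into a `TTTT|AA` endonuclease-motif site, frequent 5′ truncation,
and in ~20 % of events a twin-priming internal inversion with 1–4 bp of
junction microhomology. This package implements the full computational
workflow for finding and characterising such events, for cancer-genomics
analysts working with tumour / matched-normal / unmatched-panel
alignments:

- **Genome mode** — read pairs aligned to the transcriptome are projected
  back to genome space (introns become `N` CIGAR operations); retained
  pairs must have an insert size of 300 bp–50 kb, ≤ 2 CIGAR splits with
  terminal matches ≥ 10 bp, and MAPQ ≥ 10; a gene with > 3 supporting
  tumour pairs and zero normal/panel pairs is a candidate. A reported
  event must represent ≥ 3 exons of one gene with ≥ 2 directly observed
  canonical splice junctions.
- **Exome mode** — clusters of properly oriented pairs skipping annotated
  introns (apparent deletions of 500 bp–50 kb); ≥ 2 clusters in one gene
  involving ≥ 3 exons, vetoed by matched-normal/panel support or overlap
  with known germline deletion intervals (BED).
- **Insertion-site mapping** — discordant links plus soft-clip
  realignment (an internal 13 bp exact-seed-and-extend aligner) resolve
  both junctions to the base pair and call TSD/deletion/blunt class,
  polyA length, motif window, inversion structure and microhomologies.
- **Catalogue statistics** — patient/cell-line collapsing, the headline
  fractions (truncation, TSD, inversion, insertion contexts), and a
  top-quartile / Wilcoxon rank-sum expression-enrichment test for
  template genes.
- **Simulator** — a first-class, deterministic generator of synthetic
  genomes, retrocopy insertions and tumour/normal paired-end reads with
  exactly these mechanistic features, emitting its own SAM alignment
  representation so the whole pipeline runs without external aligners.

## Worked example

`examples/05_catalogue_summary.py` recomputes the headline statistics of
the packaged catalogue of 42 somatic processed pseudogenes found across
660 cancer samples:

```text
events: 42 in 14 primary patients and 3 cell lines
5'-truncated (not full length): 74%
internally inverted (twin priming): 21%
target-site duplications: 16/24 (67%) of fully mapped sites
mapped insertion sites: 31, of which 9 intronic and 3 in 3' UTRs
cohort frequency: 2.6% of 660 samples
lung: 19% of 27; colorectal: 18% of 11
```

Reading: three quarters of somatic retrocopies lack the complete coding
sequence (reverse transcription aborts before the 5′ end); two thirds of
the fully resolved insertion sites show the TSD hallmark of L1
endonuclease nicking; lung and colorectal cancers are the most affected
tissue types.

`examples/03_map_insertion_sites.py` runs the simulator and the full
detection + mapping stack, then compares against ground truth:

```text
gene      site-class            5'bp     3'bp   TSD  polyA  motif  inv  mh5  truth-ok
GENE001   target_site_deletion    86437    87215    0     52 True   False 0    True
GENE002   target_site_deletion   105857   105070    0      0 True   False 0    True
GENE003   TSD                    118268   118281   13     61 True   True 1    True
```

Every junction is recovered at single-base resolution (`truth-ok`), with
the TSD length, polyA tail, endonuclease-motif flag, inversion status
and 5′ microhomology read directly off the soft-clipped reads.

The other examples cover simulation (`01`), genome-mode detection with
per-filter attrition (`02`), exome mode with germline exclusion (`04`),
expression enrichment (`06`) and the 13-mer expressed-junction resolver
(`07`). A thin CLI wraps the same functions:

```bash
retrocopy simulate --out sim/ --seed 1
retrocopy detect-genome --tumour sim/tumour.transcriptome.sam \
    --normal sim/normal.transcriptome.sam --panel sim/panel1.transcriptome.sam \
    --gtf sim/genes.gtf --out events.tsv
retrocopy summarize --catalogue events.tsv --out summary.json
```

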