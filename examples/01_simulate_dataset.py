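"""Generate a synthetic tumour/normal dataset with engineered retrocopies.

Builds a small genome with spliced genes, inserts LINE-mediated retrocopy
events (5' truncation, polyA tails, target-site duplications, twin-priming
inversions, TTTTAA motif sites) and emits paired-end reads for a tumour,
its matched normal, and an unmatched-normal panel.
"""

import tempfile

from retrocopy import SimConfig, simulate_dataset

config = SimConfig(seed=42, n_chroms=1, chrom_length=120_000, n_genes=6,
                   n_events=3, coverage=20, normal_coverage=15,
                   panel_samples=1, panel_coverage=5)

with tempfile.TemporaryDirectory() as tmp:
    result = simulate_dataset(config, tmp)
    print(f"genome: {config.n_chroms} chromosome(s) x {config.chrom_length} bp, "
          f"{len(result.models)} genes")
    print(f"reads:  {result.samples['tumour']['pairs']} tumour pairs at "
          f"{config.coverage}x\n")
    print("engineered events (truth records):")
    for t in result.truths:
        j = t.event.junction
        print(f"  {t.event.source_gene}: exons {t.event.exon_span_string()}, "
              f"{t.site_class} ({t.tsd_len or t.deletion_len} bp), "
              f"polyA {t.polyA_len} bp, "
              f"{'inverted' if t.inversion_k is not None else 'not inverted'}, "
              f"insertion {t.chrom}:{t.event.insertion_point}, "
              f"motif match {j.motif_match}")

# Each line is one simulated processed pseudogene: which exons of the
# source gene were copied, how the genomic junction is structured, and
# whether the L1 endonuclease motif flanks the polyA insertion point.
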