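"""Breakpoint resolution and mechanistic feature calls."""

import numpy as np
import pytest

import retrocopy as rc
from retrocopy.breakpoints import (GenomeKmerIndex, classify_site,
                                   collect_insertion_evidence,
                                   detect_inversion, detect_polyA,
                                   map_insertion_site, microhomology,
                                   motif_window, realign_clip,
                                   resolve_expressed_junction)
from retrocopy.models import RetrocopyEvent, revcomp

from conftest import mk_gene, mk_mate, mk_pair


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestMicrohomology:
    def test_constructed_overlap(self):
        assert microhomology("GGGACGT", "ACGTCCC") == 4

    def test_no_shared_bases(self):
        assert microhomology("AAAA", "CCCC") == 0

    def test_brute_force_agreement(self, rng):
        def brute(left, right):
            best = 0
            for h in range(1, min(len(left), len(right)) + 1):
                if left[-h:] == right[:h]:
                    best = h
            return best

        for _ in range(2000):
            left, right = random_dna(rng, 20), random_dna(rng, 20)
            assert microhomology(left, right) == brute(left, right)

    def test_revcomp_symmetry(self, rng):
        """mh(x, y) is invariant under reverse-complementing the junction."""
        for _ in range(500):
            x, y = random_dna(rng, 15), random_dna(rng, 15)
            assert microhomology(x, y) == microhomology(revcomp(y), revcomp(x))


class TestPolyA:
    def test_long_run_measured(self):
        assert detect_polyA(["A" * 55 + "GCGTACGT"]) == 55

    def test_below_minimum_is_zero(self):
        assert detect_polyA(["A" * 8 + "GCGT"]) == 0

    def test_mismatch_tolerance(self):
        # AAAAGAAAA: one mismatch in nine at 10% tolerance -> run of 9
        assert detect_polyA(["AAAAGAAAA"], min_run=5) == 9

    def test_impure_run_rejected(self):
        assert detect_polyA(["AAGAAGAAGAAG"]) == 0


class TestClassifySite:
    REF = "ACGTACGTAC" * 2000

    def test_overlapping_breakpoints_are_tsd(self):
        j = classify_site(five_bp=1010, three_bp=1000, chrom="c",
                          refseq=self.REF, insert_strand="+")
        assert j.site_class == rc.SITE_TSD
        assert j.tsd_length == 10
        assert j.tsd_sequence == self.REF[1000:1010]

    def test_coincident_breakpoints_are_blunt(self):
        j = classify_site(1000, 1000, "c", self.REF)
        assert j.site_class == rc.SITE_BLUNT

    def test_gap_is_target_site_deletion(self):
        j = classify_site(1000, 9000, "c", self.REF, insert_strand="+")
        assert j.site_class == rc.SITE_DELETION
        assert j.deletion_length == 8000

    def test_minus_strand_swaps_flanks(self):
        j = classify_site(five_bp=1000, three_bp=1010, chrom="c",
                          refseq=self.REF, insert_strand="-")
        assert j.site_class == rc.SITE_TSD and j.tsd_length == 10


class TestMotifWindow:
    def test_consensus_match(self):
        ref = "G" * 50 + "TTTTAA" + "G" * 50
        window, fuzzy, exact = motif_window(54, ref, "+")
        assert fuzzy and exact
        assert window == ref[44:64]

    def test_gc_rich_no_match(self):
        ref = "GCGCGC" * 30
        _, fuzzy, exact = motif_window(90, ref, "+")
        assert not fuzzy and not exact

    def test_window_truncated_at_contig_end(self):
        ref = "TTTTAAGGG"
        window, _, _ = motif_window(4, ref, "+")
        assert window == ref[0:14]


class TestRealignClip:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.cdna = random_dna(rng, 800)

    def test_exact_suffix_clip(self):
        clip = self.cdna[:30]
        hit = realign_clip(clip, {"cdna": self.cdna}, side="suffix")
        assert hit.reason is None
        assert hit.strand == "+" and hit.junction_pos == 0

    def test_prefix_clip_end_coordinate(self):
        clip = self.cdna[-30:]
        hit = realign_clip(clip, {"cdna": self.cdna}, side="prefix")
        assert hit.reason is None
        assert hit.junction_pos == len(self.cdna) - 1

    def test_reverse_strand_hit(self):
        clip = revcomp(self.cdna[100:140])
        hit = realign_clip(clip, {"cdna": self.cdna}, side="suffix")
        assert hit.reason is None and hit.strand == "-"
        assert hit.junction_pos == 139  # clip start abuts cDNA base 139

    def test_short_clip_rejected(self):
        assert realign_clip("ACGTACGTACGT", {"c": self.cdna},
                            side="suffix").reason == "too_short"

    def test_ambiguous_hit_multimaps(self):
        seg = self.cdna[50:80]
        target = self.cdna + "N" * 10 + seg + "GG"
        hit = realign_clip(seg, {"c": target}, side="suffix")
        assert hit.reason == "multimap"

    def test_mismatch_tolerant_extension(self):
        clip = list(self.cdna[200:260])
        clip[40] = "A" if clip[40] != "A" else "C"   # one error in 60 bp
        hit = realign_clip("".join(clip), {"cdna": self.cdna}, side="suffix")
        assert hit.reason is None and hit.extended == 60


class TestInsertionMapping:
    def test_truth_junctions_recovered_exactly(self, pipeline_result):
        rec = pipeline_result.recovery
        assert rec.n_breakpoints_exact == rec.n_breakpoints_comparable
        assert rec.n_tsd_exact == rec.n_tsd_comparable

    def test_no_links_reports_unmapped(self, sim_result):
        model = sim_result.models[0]
        ev = RetrocopyEvent(source_gene=model.gene_id, sample="t")
        out = map_insertion_site(ev, model, [], sim_result.reference)
        assert not out.mapped and "no_links" in out.notes

    def test_repetitive_links_unmappable(self, sim_result):
        """Links whose away mates have zero mapping quality (repeats)
        do not map an insertion site."""
        model = sim_result.models[0]
        exon = model.exons[0]
        pairs = [
            mk_pair(
                mk_mate(chrom=model.chrom, pos=exon[0], cigar="75M"),
                mk_mate(chrom=model.chrom, pos=exon[0] + 20_000, cigar="75M",
                        strand="-", mapq=0),
                name=f"r{i}",
            )
            for i in range(4)
        ]
        ev = RetrocopyEvent(source_gene=model.gene_id, sample="t")
        out = map_insertion_site(ev, model, pairs, sim_result.reference)
        assert not out.mapped and "unmapped" in out.notes

    def test_polyA_detected_when_tail_present(self, pipeline_result):
        truths = {t.event.source_gene: t for t in pipeline_result.sim.truths}
        for ev in pipeline_result.events:
            t = truths[ev.source_gene]
            if t.polyA_len >= 30 and ev.junction and ev.junction.fully_mapped:
                assert ev.junction.polyA_length >= 10

    def test_motif_flag_matches_truth(self, pipeline_result):
        truths = {t.event.source_gene: t for t in pipeline_result.sim.truths}
        for ev in pipeline_result.events:
            j = ev.junction
            if j is not None and j.fully_mapped:
                assert j.motif_match == truths[ev.source_gene].event.junction.motif_match


@pytest.fixture(scope="module")
def tumour_pairs(sim_result):
    pairs, _ = rc.read_alignments(sim_result.sam("tumour"), "tumour")
    return pairs


class TestInversion:
    def test_twin_priming_round_trip(self, sim_result, tumour_pairs):
        """Simulated inversions are detected with the internal breakpoint
        at the truth position, correct microhomology, and without
        duplicated template evidence."""
        by_tid = {m.transcript_id: m for m in sim_result.models}
        checked = 0
        for t in sim_result.truths:
            if t.inversion_k is None:
                continue
            model = by_tid[t.transcript_id]
            cdna = model.spliced_sequence(sim_result.reference[model.chrom])
            _, clips = collect_insertion_evidence(model, tumour_pairs)
            exonic = [c for c in clips
                      if model.genome_to_transcript(c.anchor_pos) is not None]
            call = detect_inversion(model, cdna, exonic)
            assert call.inverted
            assert call.internal_junction_t == t.inversion_k
            assert call.truncation_t == t.t_trunc
            assert call.micro_internal == t.mh_internal
            assert call.no_duplication
            checked += 1
        assert checked >= 1

    def test_non_inverted_events_stay_uninverted(self, pipeline_result):
        truths = {t.event.source_gene: t for t in pipeline_result.sim.truths}
        for ev in pipeline_result.events:
            assert ev.inverted == (truths[ev.source_gene].inversion_k is not None)


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(123)
    ga = list(random_dna(rng, 4000))
    gb = list(random_dna(rng, 4000))
    # pin the bases flanking the engineered junctions so that no chance
    # microhomology blurs the expected breakpoint coordinates
    ga[999], ga[1000], ga[1039], ga[1040] = "A", "A", "A", "A"
    gb[2499], gb[2500] = "C", "C"
    return {"chrA": "".join(ga), "chrB": "".join(gb)}


@pytest.fixture(scope="module")
def index(small_genome):
    return GenomeKmerIndex(small_genome)


class TestExpressedJunction:
    def test_chimeric_read_junction_at_truth(self, small_genome, index):
        """A cDNA|host-UTR chimera resolves to the exact breakpoint."""
        left = small_genome["chrA"][1000:1040]
        right = small_genome["chrB"][2500:2535]
        junctions = resolve_expressed_junction([left + right], {}, index)
        assert junctions == [(("chrA", 1039), ("chrB", 2500))]

    def test_transcriptomic_read_consumed(self, small_genome, index):
        tx = {"t1": small_genome["chrA"][500:1500]}
        read = small_genome["chrA"][700:775]
        assert resolve_expressed_junction([read], tx, index) == []
        assert resolve_expressed_junction([revcomp(read)], tx, index) == []

    def test_repeat_read_unresolved(self, index):
        read = "AT" * 40  # no unique 13-mer anchor
        assert resolve_expressed_junction([read], {}, index) == []

    def test_reverse_strand_fragment_located(self, small_genome, index):
        left = revcomp(small_genome["chrA"][1000:1040])
        right = small_genome["chrB"][2500:2535]
        junctions = resolve_expressed_junction([left + right], {}, index)
        assert junctions == [(("chrA", 1000), ("chrB", 2500))]
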