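"""Whole-genome mode: pair filters, gene assignment, candidate calling."""

import dataclasses

import pytest

import retrocopy as rc
from retrocopy.genome_mode import (FilterThresholds, GeneIndex, assign_to_gene,
                                   call_candidates, count_splice_junctions,
                                   pass_pair_filters)
from retrocopy.pipeline import load_projected_pairs

from conftest import mk_gene, mk_mate, mk_pair

T = FilterThresholds()


def _pair(pos1=1000, pos2=11_000, cigar1="75M", cigar2="75M", mapq=37):
    return mk_pair(mk_mate(pos=pos1, cigar=cigar1, mapq=mapq),
                   mk_mate(pos=pos2, cigar=cigar2, strand="-", mapq=mapq))


class TestPairFilters:
    def test_good_pair_passes(self):
        ok, reasons = pass_pair_filters(
            _pair(pos1=1000, pos2=10_925, cigar1="40M2000N35M"), T)
        assert ok and not reasons

    @pytest.mark.parametrize("kwargs,reason", [
        (dict(pos2=1175), "insert_too_small"),          # span 250
        (dict(pos2=60_000), "insert_too_large"),
        (dict(cigar1="9M1000N66M"), "terminal_match"),
        (dict(cigar1="20M100N20M100N20M100N15M"), "cigar_splits"),
        (dict(mapq=9), "mapq"),
    ])
    def test_failure_reasons(self, kwargs, reason):
        ok, reasons = pass_pair_filters(_pair(**kwargs), T)
        assert not ok and reason in reasons

    def test_boundary_values_inclusive(self):
        assert pass_pair_filters(_pair(pos2=1225), T)[0]          # span == 300
        assert pass_pair_filters(_pair(pos2=49_925), T)[0]        # span == 50000
        assert pass_pair_filters(_pair(cigar1="10M500N65M"), T)[0]
        assert pass_pair_filters(_pair(mapq=10), T)[0]


class TestGeneAssignment:
    INDEX = GeneIndex([
        mk_gene([(1000, 1500), (9000, 9500), (19_000, 20_000)], gene_id="GA"),
        mk_gene([(19_500, 19_800), (25_000, 26_000)], gene_id="GB"),
        mk_gene([(40_000, 41_000), (45_000, 46_000)], gene_id="NC",
                biotype="lincRNA"),
    ])

    def test_both_mates_inside_one_gene(self):
        pair = _pair(pos1=1100, pos2=9100)
        assert assign_to_gene(pair, self.INDEX) == ["GA"]

    def test_one_base_past_gene_end_excluded(self):
        pair = _pair(pos1=1100, pos2=20_000 - 74)  # mate2 end = 20001
        assert assign_to_gene(pair, self.INDEX) == []

    def test_overlapping_genes_both_reported(self):
        pair = _pair(pos1=19_500, pos2=19_700)
        assert assign_to_gene(pair, self.INDEX) == ["GA", "GB"]

    def test_non_coding_gene_ignored(self):
        pair = _pair(pos1=40_100, pos2=45_100)
        assert assign_to_gene(pair, self.INDEX) == []


class TestCandidateCalling:
    GENE = mk_gene([(1000, 1500), (9000, 9500), (19_000, 20_000)], gene_id="GA")

    def _pairs(self, n, sample="tumour"):
        return [mk_pair(mk_mate(pos=1100 + i, cigar="75M"),
                        mk_mate(pos=9100 + i, cigar="75M", strand="-"),
                        name=f"{sample}{i}", sample=sample)
                for i in range(n)]

    def test_four_tumour_pairs_zero_normal_is_candidate(self):
        report = call_candidates(self._pairs(4), [], [], [self.GENE])
        assert [ev.source_gene for ev in report.events] == ["GA"]
        assert report.events[0].supporting_pairs == 4

    def test_three_tumour_pairs_is_not(self):
        report = call_candidates(self._pairs(3), [], [], [self.GENE])
        assert report.events == []

    def test_single_panel_pair_vetoes(self):
        report = call_candidates(self._pairs(10), [],
                                 self._pairs(1, "panel"), [self.GENE])
        assert report.events == []

    def test_candidate_below_exon_junction_bar_demoted(self):
        # pairs touch only 2 exons and observe no splice junction
        report = call_candidates(self._pairs(5), [], [], [self.GENE])
        ev = report.events[0]
        assert ev.n_junctions_observed == 0
        assert ev.confidence == "low"


class TestSpliceJunctions:
    # five 100 bp exons every 200 bp, like the fully recovered example
    # where all four canonical junctions were crossed by reads
    GENE5 = mk_gene([(i * 200, i * 200 + 100) for i in range(5)], gene_id="G5")

    def _crossing_pair(self, i):
        # read ends 20 bp into exon i, 20 bp into exon i+1
        m1 = mk_mate(pos=i * 200 + 80, cigar="20M100N20M")
        m2 = mk_mate(pos=(i + 1) * 200 + 50, cigar="40M", strand="-")
        return mk_pair(m1, m2, name=f"x{i}")

    def test_all_four_junctions_counted(self):
        pairs = [self._crossing_pair(i) for i in range(4)]
        assert count_splice_junctions([self.GENE5], pairs) == 4

    def test_no_split_reads_counts_zero(self):
        pairs = [mk_pair(mk_mate(pos=10, cigar="40M"),
                         mk_mate(pos=220, cigar="40M", strand="-"))]
        assert count_splice_junctions([self.GENE5], pairs) == 0

    def test_off_boundary_split_not_counted(self):
        m1 = mk_mate(pos=85, cigar="20M95N20M")  # skip not matching intron
        pairs = [mk_pair(m1, mk_mate(pos=250, cigar="40M", strand="-"))]
        assert count_splice_junctions([self.GENE5], pairs) == 0

    def test_simulated_junction_counts_match_truth(self, pipeline_result):
        by_gene = {t.event.source_gene: t for t in pipeline_result.sim.truths}
        for ev in pipeline_result.events:
            truth = by_gene[ev.source_gene]
            model = next(m for m in pipeline_result.sim.models
                         if m.gene_id == ev.source_gene)
            # junctions retained in the (possibly truncated) retrocopy
            retained = model.n_exons - 1 - sum(
                1 for ts, _, _, _ in model.transcript_blocks()
                if 0 < ts <= truth.t_trunc
            )
            assert ev.n_junctions_observed <= model.n_exons - 1
            assert ev.n_junctions_observed >= min(2, retained)


@pytest.fixture(scope="module")
def projected(sim_result):
    models = sim_result.models
    tum = load_projected_pairs(sim_result.sam("tumour", "transcriptome"),
                               "tumour", models)
    norm = load_projected_pairs(sim_result.sam("normal", "transcriptome"),
                                "normal", models)
    panel = []
    for name in sim_result.panel_names:
        panel += load_projected_pairs(
            sim_result.sam(name, "transcriptome"), name, models)
    return tum, norm, panel


class TestPipelineProperties:
    def test_pair_filter_relaxation_is_monotone(self, projected):
        """Any pair passing the strict filters passes relaxed ones."""
        tum, _, _ = projected
        relaxed_t = dataclasses.replace(
            FilterThresholds(), min_mapq=0, min_insert=200, max_insert=100_000,
            max_cigar_splits=5, min_terminal_match=1,
        )
        for pair in tum:
            if pass_pair_filters(pair, T)[0]:
                assert pass_pair_filters(pair, relaxed_t)[0]

    def test_candidate_set_monotone_in_quality_thresholds(self, sim_result,
                                                          projected):
        """Relaxing mapq/split/terminal-match thresholds never removes a
        candidate.  (Widening the insert window is deliberately excluded:
        it admits concordant pairs into the *normal* support counts and
        can veto candidates — the filters bind both sides.)"""
        tum, norm, panel = projected
        strict = call_candidates(tum, norm, panel, sim_result.models)
        relaxed_t = dataclasses.replace(
            FilterThresholds(), min_mapq=0, max_cigar_splits=5,
            min_terminal_match=1,
        )
        relaxed = call_candidates(tum, norm, panel, sim_result.models, relaxed_t)
        assert {e.source_gene for e in strict.events} <= {
            e.source_gene for e in relaxed.events}

    def test_normal_only_input_yields_no_candidates(self, sim_result, projected):
        _, norm, panel = projected
        report = call_candidates(norm, panel, [], sim_result.models)
        assert report.events == []

    def test_every_truth_event_recovered(self, pipeline_result):
        truth_genes = {t.event.source_gene for t in pipeline_result.sim.truths}
        called = {ev.source_gene for ev in pipeline_result.events}
        assert truth_genes <= called
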