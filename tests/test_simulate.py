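"""Synthetic-data generator: genome, retrocopy construction, reads."""

import dataclasses

import numpy as np
import pytest

import retrocopy as rc
from retrocopy.breakpoints import microhomology
from retrocopy.models import revcomp
from retrocopy.simulate import (SimConfig, _SitePicker, apply_insertions,
                                find_all, make_genome, make_retrocopy,
                                twin_prime)

SMALL = SimConfig(seed=5, n_chroms=1, chrom_length=120_000, n_genes=6,
                  n_events=2, coverage=12, normal_coverage=8,
                  panel_samples=1, panel_coverage=4)


@pytest.fixture(scope="module")
def genome_and_models():
    return make_genome(SimConfig(seed=2))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"truncation_prob": 1.5},
        {"tsd_range": (20, 8)},
        {"n_events": 99},
        {"tsd_prob": 0.9, "site_deletion_prob": 0.5},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestMakeGenome:
    def test_gene_count_and_exon_ranges(self, genome_and_models):
        _, models = genome_and_models
        cfg = SimConfig(seed=2)
        assert len(models) == cfg.n_genes
        for m in models:
            assert cfg.exons_per_gene[0] <= m.n_exons <= cfg.exons_per_gene[1]
            for s, e in m.exons:
                assert cfg.exon_length[0] <= e - s <= cfg.exon_length[1]

    def test_genes_do_not_overlap(self, genome_and_models):
        _, models = genome_and_models
        by_chrom = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_same_seed_identical_sequence(self):
        cfg = SimConfig(seed=9)
        seqs1, _ = make_genome(cfg)
        seqs2, _ = make_genome(cfg)
        assert seqs1 == seqs2

    def test_motif_density_scales_with_request(self):
        dense = SimConfig(seed=4, motif_spacing=1000)
        sparse = SimConfig(seed=4, motif_spacing=8000)
        n = {}
        for cfg in (dense, sparse):
            seqs, _ = make_genome(cfg)
            n[cfg.motif_spacing] = sum(
                len(find_all(s, "TTTTAA")) + len(find_all(s, "TTAAAA"))
                for s in seqs.values()
            )
        # planted motifs per chrom = chrom_length / spacing (plus chance
        # occurrences at rate ~2L/4^6); expectation check with wide margin
        expected_extra = 2 * 150_000 * 2 / 4096
        planted_dense = 2 * 150
        assert n[1000] > n[8000]
        assert abs(n[1000] - (planted_dense + expected_extra)) < 0.35 * (
            planted_dense + expected_extra)

    def test_oversized_genes_raise(self):
        with pytest.raises(ValueError, match="fit"):
            make_genome(SimConfig(seed=0, chrom_length=20_000))


class TestMakeRetrocopy:
    def _one(self, config, seed=3, **overrides):
        cfg = dataclasses.replace(config, **overrides)
        genome, models = make_genome(cfg)
        rng = np.random.default_rng(seed)
        picker = _SitePicker(seqs=genome, models=models)
        src = max(models, key=lambda m: m.n_exons)
        truth = make_retrocopy(src, genome, cfg, rng, picker=picker, models=models)
        return genome, models, src, truth

    def test_no_truncation_no_inversion_is_full_cdna(self):
        genome, _, src, truth = self._one(
            SimConfig(seed=2), truncation_prob=0.0, inversion_prob=0.0,
            polyA_prob=1.0,
        )
        cdna = src.spliced_sequence(genome[src.chrom])
        expected = cdna + "A" * truth.polyA_len
        got = truth.insert_seq if truth.orientation == "+" else revcomp(truth.insert_seq)
        assert got == expected
        assert truth.event.full_length

    def test_tsd_flanks_both_breakpoints(self):
        genome, models, src, truth = self._one(
            SimConfig(seed=2), tsd_prob=1.0, site_deletion_prob=0.0,
        )
        assert truth.site_class == rc.SITE_TSD
        a, b = truth.left_ref_end, truth.right_ref_start
        dup = genome[truth.chrom][b:a]
        assert len(dup) == truth.tsd_len
        tumour, _ = apply_insertions(genome, [truth], models)
        tum = tumour[truth.chrom]
        ins_start = a
        ins_end = a + len(truth.insert_seq)
        assert tum[ins_start - truth.tsd_len:ins_start] == dup
        assert tum[ins_end:ins_end + truth.tsd_len] == dup

    def test_motif_site_reads_tttt_aa(self):
        genome, _, _, truth = self._one(
            SimConfig(seed=2), motif_bias=1.0, tsd_prob=1.0,
            site_deletion_prob=0.0,
        )
        j3 = truth.event.junction.three_prime_bp
        ref = genome[truth.chrom]
        if truth.orientation == "+":
            assert ref[j3 - 4:j3 + 2] == "TTTTAA"
        else:
            assert ref[j3 - 2:j3 + 4] == "TTAAAA"
        assert truth.event.junction.motif_match

    def test_too_few_exons_rejected(self):
        from conftest import mk_gene
        g = mk_gene([(100, 300), (500, 700)])
        with pytest.raises(ValueError, match="fewer than 3"):
            make_retrocopy(g, {"chr1": "A" * 1000}, SimConfig(),
                           np.random.default_rng(0), models=[g])

    def test_truncation_leaves_three_exons(self):
        cfg = SimConfig(seed=2, truncation_prob=1.0)
        genome, models = make_genome(cfg)
        rng = np.random.default_rng(11)
        picker = _SitePicker(seqs=genome, models=models)
        for src in models[:4]:
            truth = make_retrocopy(src, genome, cfg, rng, picker=picker,
                                   models=models)
            n_exons = sum(hi - lo + 1 for lo, hi, _ in truth.event.exon_span)
            assert n_exons >= 3
            assert not truth.event.full_length or truth.t_trunc == 0


class TestTwinPrime:
    def test_no_duplication_reconstruction(self, rng):
        cdna = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        out, k, mh = twin_prime(cdna, SimConfig(), rng)
        assert revcomp(out[:k]) + out[k:] == cdna
        assert 1 <= mh <= 4
        assert mh == microhomology(revcomp(cdna[:k]), cdna[k:])

    def test_exon_order_shuffled_in_truth(self, sim_result):
        inverted = [t for t in sim_result.truths if t.inversion_k is not None]
        for t in inverted:
            strands = [s for _, _, s in t.event.exon_span]
            assert strands[0] == "-" and strands[-1] == "+"

    def test_too_short_cdna_raises(self, rng):
        with pytest.raises(ValueError):
            twin_prime("ACGT" * 10, SimConfig(), rng)


class TestApplyInsertions:
    @pytest.mark.parametrize("site,expected_delta", [
        ("blunt", 0), ("TSD", 10), ("deletion", -8000),
    ])
    def test_length_arithmetic(self, site, expected_delta):
        overrides = dict(tsd_prob=0.0, site_deletion_prob=0.0)
        if site == "TSD":
            overrides = dict(tsd_prob=1.0, site_deletion_prob=0.0,
                             tsd_range=(10, 10))
        elif site == "deletion":
            overrides = dict(tsd_prob=0.0, site_deletion_prob=1.0,
                             site_deletion_range=(8000, 8000))
        cfg = dataclasses.replace(SimConfig(seed=2), **overrides)
        genome, models = make_genome(cfg)
        rng = np.random.default_rng(17)
        picker = _SitePicker(seqs=genome, models=models)
        src = max(models, key=lambda m: m.n_exons)
        truth = make_retrocopy(src, genome, cfg, rng, picker=picker, models=models)
        tumour, _ = apply_insertions(genome, [truth], models)
        delta = sum(len(tumour[c]) - len(genome[c]) for c in genome)
        assert delta == len(truth.insert_seq) + expected_delta

    def test_overlapping_sites_error(self, sim_result):
        t = sim_result.truths[0]
        clone = dataclasses.replace(t)
        with pytest.raises(ValueError, match="overlap"):
            apply_insertions(sim_result.reference, [t, clone], sim_result.models)

    def test_insert_conservation(self, sim_result):
        """Every truth insert is reconstructable from its description."""
        by_tid = {m.transcript_id: m for m in sim_result.models}
        for t in sim_result.truths:
            model = by_tid[t.transcript_id]
            full = model.spliced_sequence(sim_result.reference[model.chrom])
            assert t.reconstruct_insert(full) == t.insert_seq


class TestGenerateReads:
    def test_reference_read_full_match(self, sim_result):
        pairs, _ = rc.read_alignments(sim_result.sam("normal"), "normal")
        assert all(
            len(m.cigar_ops) == 1 and m.cigar_ops[0][0] == "M"
            for p in pairs[:500] for m in p.mates
        )

    def test_junction_read_clip_matches_insert(self, sim_result):
        """A read straddling the 5' junction is soft-clipped and the
        clipped bases equal the insert prefix."""
        truth = next(t for t in sim_result.truths if t.orientation == "+")
        a = truth.left_ref_end
        pairs, _ = rc.read_alignments(sim_result.sam("tumour"), "tumour")
        found = 0
        for p in pairs:
            for m in p.mates:
                if (m.is_mapped and m.chrom == truth.chrom and m.end == a
                        and len(m.clipped_suffix) >= 20):
                    clip = m.clipped_suffix
                    expect = truth.insert_seq[:len(clip)]
                    mismatches = sum(x != y for x, y in zip(clip, expect))
                    assert mismatches <= 2  # sequencing-error tolerance
                    found += 1
        assert found >= 1

    def test_coverage_near_request(self, sim_result):
        cfg = sim_result.config
        pairs, _ = rc.read_alignments(sim_result.sam("normal"), "normal")
        lo, hi = 40_000, 60_000
        bases = sum(
            max(0, min(m.end, hi) - max(m.pos, lo))
            for p in pairs for m in p.mates if m.is_mapped and m.chrom == "chr1"
        )
        depth = bases / (hi - lo)
        assert abs(depth - cfg.normal_coverage) / cfg.normal_coverage < 0.10

    def test_dataset_determinism(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        rc.simulate_dataset(SMALL, d1)
        rc.simulate_dataset(SMALL, d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p2.read_bytes() == p1.read_bytes(), p1.name
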