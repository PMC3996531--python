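"""Insertion context, catalogue summary, expression enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

import retrocopy as rc
from retrocopy.annotate import (CTX_INTERGENIC, CTX_INTRON, CTX_UPSTREAM,
                                CTX_UTR3, annotate_insertion, cohort_frequency,
                                expression_enrichment, patient_of,
                                summarize_catalogue)

from conftest import mk_gene


class TestInsertionContext:
    # a 12-exon host: 100 bp exons every 300 bp, CDS from exon 1 to 11
    HOST = mk_gene([(i * 300, i * 300 + 100) for i in range(12)],
                   gene_id="HOST", cds=(50, 3330))

    def test_intron_11_opposite_orientation(self):
        point = 11 * 300 - 100  # inside intron 11 (between exons 11 and 12)
        [ctx] = annotate_insertion(("chr1", point), [self.HOST],
                                   insert_strand="-")
        assert ctx.klass == CTX_INTRON
        assert ctx.feature_index == 11
        assert ctx.host_gene == "HOST"
        assert ctx.orientation_vs_host == "opposite"

    def test_utr3_of_final_exon(self):
        [ctx] = annotate_insertion(("chr1", 3340), [self.HOST],
                                   insert_strand="+")
        assert ctx.klass == CTX_UTR3
        assert ctx.orientation_vs_host == "same"

    def test_shared_utr3_of_two_overlapping_genes(self):
        # two opposite-strand genes whose final exons overlap
        ga = mk_gene([(0, 200), (500, 800)], gene_id="GA", strand="+",
                     cds=(50, 600))
        gb = mk_gene([(700, 900), (1200, 1400)], gene_id="GB", strand="-",
                     cds=(850, 1300))
        ctxs = annotate_insertion(("chr1", 750), [ga, gb], insert_strand="+")
        assert {c.host_gene for c in ctxs} == {"GA", "GB"}
        assert {c.klass for c in ctxs} == {CTX_UTR3}
        assert {c.orientation_vs_host for c in ctxs} == {"same", "opposite"}

    def test_upstream_window(self):
        ctxs = annotate_insertion(("chr1", 4000), [self.HOST])
        # 4 kb past the gene end of a plus-strand gene: not upstream
        assert ctxs[0].klass == CTX_INTERGENIC
        minus = mk_gene([(0, 100), (300, 400)], gene_id="M", strand="-")
        [ctx] = annotate_insertion(("chr1", 2000), [minus])
        assert ctx.klass == CTX_UPSTREAM

    def test_far_from_any_gene_is_intergenic(self):
        [ctx] = annotate_insertion(("chr1", 50_000), [self.HOST])
        assert ctx.klass == CTX_INTERGENIC
        assert ctx.host_gene is None


class TestSummary:
    def test_row_order_invariance(self):
        cat = rc.read_catalogue(rc.PUBLISHED_CATALOGUE).rows
        shuffled = cat.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert summarize_catalogue(cat) == summarize_catalogue(shuffled)

    def test_empty_catalogue_all_zero(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(rc.io.CATALOGUE_COLUMNS) + "\n")
        s = summarize_catalogue(rc.read_catalogue(path))
        assert s["n_events"] == 0
        assert s["pct_not_full_length"] is None

    def test_patient_collapsing(self):
        assert patient_of("PD7354c") == ("PD7354", False)
        assert patient_of("PD7354h") == ("PD7354", False)
        assert patient_of("NCI-H2009", "Cell line (lung)") == ("NCI-H2009", True)

    def test_polyA_column_used_when_present(self):
        cat = rc.read_catalogue(rc.PUBLISHED_CATALOGUE).rows.copy()
        cat["polyA"] = "Yes"
        s = summarize_catalogue(cat)
        assert s["pct_polyA_fully_mapped"] == pytest.approx(100.0)

    def test_cohort_frequency(self):
        assert cohort_frequency(17, 660) == pytest.approx(100 * 17 / 660)
        with pytest.raises(ValueError):
            cohort_frequency(1, 0)


def brute_force_rank_sum_p(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumeration over all C(n+m, n) assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = np.sum(ranks[:n]) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        u = np.sum(ranks[list(combo)]) - n * (n + 1) / 2
        us.append(u)
    us = np.asarray(us)
    p_ge = np.mean(us >= u_obs)
    p_le = np.mean(us <= u_obs)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestExpressionEnrichment:
    def _cohort(self, rng, n=200):
        vals = rng.lognormal(0, 1, n)
        return {f"G{i}": float(v) for i, v in enumerate(vals)}

    def test_extreme_template_set(self, rng):
        expr = self._cohort(rng)
        top = max(expr.values())
        for i in range(10):
            expr[f"T{i}"] = top + 1 + i
        frac, p = expression_enrichment([f"T{i}" for i in range(10)], expr)
        assert frac == 1.0
        assert p < 1e-3

    def test_top_decile_construction(self, rng):
        expr = self._cohort(rng, 300)
        ranked = sorted(expr, key=expr.get, reverse=True)
        template = ranked[:30]
        frac, p = expression_enrichment(template, expr)
        assert frac == 1.0
        assert p < 1e-6

    def test_quartile_boundary_counts_as_top(self):
        expr = {f"G{i}": float(i) for i in range(8)}
        q75 = np.percentile(list(expr.values()), 75)
        gene_at_threshold = [g for g, v in expr.items() if v == q75]
        if gene_at_threshold:
            frac, _ = expression_enrichment(gene_at_threshold, expr)
            assert frac == 1.0

    def test_missing_genes_dropped_with_log(self, rng, caplog):
        import logging
        expr = self._cohort(rng, 50)
        with caplog.at_level(logging.WARNING):
            frac, p = expression_enrichment(["G0", "G1", "NOPE"], expr)
        assert "missing" in caplog.text

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            expression_enrichment(["A"], {"A": 1.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("n,m", [(4, 5), (6, 6), (8, 7), (8, 8)])
    def test_exact_p_matches_brute_force_enumeration(self, n, m, rng):
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            expr = {f"T{i}": float(v) for i, v in enumerate(x)}
            expr.update({f"B{i}": float(v) for i, v in enumerate(y)})
            _, p = expression_enrichment(list(expr)[:n], expr)
            assert p == pytest.approx(brute_force_rank_sum_p(x, y), abs=1e-12)
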