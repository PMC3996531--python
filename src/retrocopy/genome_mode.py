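"""Whole-genome retrocopy detection from projected read pairs.

Transcriptome-aligned read pairs, projected back to genome space, are
filtered on insert size, CIGAR splits, terminal match length and mapping
quality; pairs whose four coordinates all fall inside one protein-coding
gene are counted per gene, and genes with tumour support but no support
in the matched normal or unmatched-normal panel become candidate somatic
retrocopies.  A reported event must represent at least three exons of a
single gene with at least two directly observed canonical splice
junctions; candidates below that bar are demoted to low confidence, not
silently dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .liftover import genome_insert_size
from .models import AlignedPair, GeneModel, RetrocopyEvent


@dataclass(frozen=True)
class FilterThresholds:
    """Read-pair filter settings; defaults are the published values."""

    min_insert: int = 300
    max_insert: int = 50_000
    max_cigar_splits: int = 2
    min_terminal_match: int = 10
    min_mapq: int = 10
    min_tumour_pairs: int = 4        # "more than three supporting reads"
    max_normal_pairs: int = 0
    min_event_exons: int = 3
    min_event_junctions: int = 2

    def __post_init__(self) -> None:
        if self.min_insert >= self.max_insert:
            raise ValueError("min_insert must be < max_insert")


def pass_pair_filters(
    pair: AlignedPair, t: FilterThresholds
) -> tuple[bool, list[str]]:
    """Apply the per-pair filters; returns (passed, failure reason codes)."""
    reasons: list[str] = []
    if not (pair.mate1.is_mapped and pair.mate2.is_mapped):
        return False, ["unmapped_mate"]
    size = genome_insert_size(pair)
    if size is None:
        reasons.append("different_chromosomes")
    elif size < t.min_insert:
        reasons.append("insert_too_small")
    elif size > t.max_insert:
        reasons.append("insert_too_large")
    for m in pair.mates:
        if m.n_splits > t.max_cigar_splits:
            reasons.append("cigar_splits")
            break
    for m in pair.mates:
        blocks = m.match_blocks
        if not blocks or blocks[0] < t.min_terminal_match or blocks[-1] < t.min_terminal_match:
            reasons.append("terminal_match")
            break
    if min(pair.mate1.mapq, pair.mate2.mapq) < t.min_mapq:
        reasons.append("mapq")
    return (not reasons), reasons


class GeneIndex:
    """Gene footprints (transcript-union spans) on an interval tree."""

    def __init__(
        self, models: Iterable[GeneModel], protein_coding_only: bool = True
    ) -> None:
        spans: dict[str, list] = {}
        self.models_by_gene: dict[str, list[GeneModel]] = defaultdict(list)
        for m in models:
            if protein_coding_only and m.biotype != "protein_coding":
                continue
            self.models_by_gene[m.gene_id].append(m)
            cur = spans.get(m.gene_id)
            if cur is None:
                spans[m.gene_id] = [m.chrom, m.start, m.end]
            else:
                cur[1] = min(cur[1], m.start)
                cur[2] = max(cur[2], m.end)
        self.span_by_gene = {g: (c, s, e) for g, (c, s, e) in spans.items()}
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for gid, (chrom, s, e) in self.span_by_gene.items():
            self.trees[chrom].addi(s, e, gid)

    def genes_containing(self, chrom: str, *positions: int) -> list[str]:
        """Gene ids whose footprint contains every given position."""
        if not positions:
            return []
        hits: Optional[set[str]] = None
        for p in positions:
            here = {iv.data for iv in self.trees.get(chrom, IntervalTree()).at(p)}
            hits = here if hits is None else hits & here
            if not hits:
                return []
        return sorted(hits)

    def primary_model(self, gene_id: str) -> GeneModel:
        """Longest transcript of the gene (exon-count, then length)."""
        return max(
            self.models_by_gene[gene_id],
            key=lambda m: (m.n_exons, m.transcript_length),
        )


def assign_to_gene(pair: AlignedPair, index: GeneIndex) -> list[str]:
    """Genes containing all four pair coordinates (both mates' start/end).

    Overlapping genes both containing the pair are all returned; the pair
    then supports a candidate in each.
    """
    if not pair.same_chrom:
        return []
    return index.genes_containing(
        pair.mate1.chrom,
        pair.mate1.pos, pair.mate1.end - 1,
        pair.mate2.pos, pair.mate2.end - 1,
    )


def count_splice_junctions(
    gene_models: Iterable[GeneModel], pairs: Iterable[AlignedPair]
) -> int:
    """Distinct annotated exon-exon junctions crossed by split reads.

    A junction counts only when a read's N operation coincides exactly
    with annotated exon boundaries on both sides.
    """
    annotated: set[tuple[int, int]] = set()
    for m in gene_models:
        annotated |= m.splice_junctions()
    seen: set[tuple[int, int]] = set()
    for pair in pairs:
        for mate in pair.mates:
            for iv in mate.skipped_intervals():
                if iv in annotated:
                    seen.add(iv)
    return len(seen)


def _observed_exons(model: GeneModel, pairs: Iterable[AlignedPair]) -> set[int]:
    exons: set[int] = set()
    order = model.exons_in_transcription_order()
    for pair in pairs:
        for mate in pair.mates:
            if mate.chrom != model.chrom:
                continue
            for blo, bhi in mate.reference_blocks():
                for i, (s, e) in enumerate(order, start=1):
                    if blo < e and s < bhi:
                        exons.add(i)
    return exons


def _runs(indices: set[int]) -> list[tuple[int, int, str]]:
    out = []
    for i in sorted(indices):
        if out and i == out[-1][1] + 1:
            out[-1] = (out[-1][0], i, "+")
        else:
            out.append((i, i, "+"))
    return out


@dataclass
class DetectionReport:
    events: list[RetrocopyEvent]
    attrition: dict[str, int] = field(default_factory=dict)
    support: dict[str, dict[str, int]] = field(default_factory=dict)
    supporting_pairs: dict[str, list[AlignedPair]] = field(default_factory=dict)


def call_candidates(
    tumour_pairs: Iterable[AlignedPair],
    normal_pairs: Iterable[AlignedPair],
    panel_pairs: Iterable[AlignedPair],
    models: Iterable[GeneModel],
    thresholds: FilterThresholds = FilterThresholds(),
    protein_coding_only: bool = True,
    sample: str = "tumour",
) -> DetectionReport:
    """Run the per-gene counting step and emit candidate events.

    A gene is a candidate iff the tumour has at least ``min_tumour_pairs``
    supporting pairs and the matched normal plus panel together have at
    most ``max_normal_pairs`` (default zero).
    """
    models = list(models)
    index = GeneIndex(models, protein_coding_only=protein_coding_only)
    attrition: dict[str, int] = defaultdict(int)
    support: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    tumour_by_gene: dict[str, list[AlignedPair]] = defaultdict(list)

    def _tally(pairs: Iterable[AlignedPair], label: str) -> None:
        for pair in pairs:
            attrition[f"{label}_pairs"] += 1
            ok, reasons = pass_pair_filters(pair, thresholds)
            if not ok:
                for r in reasons:
                    attrition[f"{label}_fail_{r}"] += 1
                continue
            genes = assign_to_gene(pair, index)
            if not genes:
                attrition[f"{label}_fail_no_gene"] += 1
                continue
            attrition[f"{label}_retained"] += 1
            for g in genes:
                support[g][label] += 1
                if label == "tumour":
                    tumour_by_gene[g].append(pair)

    _tally(tumour_pairs, "tumour")
    _tally(normal_pairs, "normal")
    _tally(panel_pairs, "panel")

    events: list[RetrocopyEvent] = []
    supporting: dict[str, list[AlignedPair]] = {}
    for gene_id, counts in support.items():
        n_tum = counts.get("tumour", 0)
        n_norm = counts.get("normal", 0) + counts.get("panel", 0)
        if n_tum < thresholds.min_tumour_pairs or n_norm > thresholds.max_normal_pairs:
            continue
        gene_models = index.models_by_gene[gene_id]
        primary = index.primary_model(gene_id)
        pairs_here = tumour_by_gene[gene_id]
        exons = _observed_exons(primary, pairs_here)
        n_junc = count_splice_junctions(gene_models, pairs_here)
        ok = (len(exons) >= thresholds.min_event_exons
              and n_junc >= thresholds.min_event_junctions)
        events.append(
            RetrocopyEvent(
                source_gene=gene_id,
                sample=sample,
                exon_span=_runs(exons),
                full_length=(len(exons) == primary.n_exons),
                supporting_pairs=n_tum,
                supporting_splits=sum(
                    1 for p in pairs_here for m in p.mates if m.n_splits
                ),
                n_exons_observed=len(exons),
                n_junctions_observed=n_junc,
                confidence="high" if ok else "low",
            )
        )
        supporting[gene_id] = pairs_here
    order = {
        gid: (index.span_by_gene[gid][0], index.span_by_gene[gid][1], gid)
        for gid in supporting
    }
    events.sort(key=lambda ev: order[ev.source_gene])
    return DetectionReport(
        events=events, attrition=dict(attrition),
        support={g: dict(c) for g, c in support.items()},
        supporting_pairs=supporting,
    )
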