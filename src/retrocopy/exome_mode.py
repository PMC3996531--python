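"""Exome-mode retrocopy detection via intragenic deletion-like pairs.

Exome capture covers exons but not introns, so a retrocopy shows up as
properly oriented read pairs whose genomic span skips one or more
annotated introns — apparent deletions.  Pairs skipping the same
intron(s) are clustered; a gene with at least two such clusters (spans
between 500 bp and 50 kb, jointly involving at least three exons)
becomes a candidate, and candidates are vetoed by any supporting pair in
the matched normal or unmatched panel, or by overlap of the skipped
intron with a known germline deletion interval.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .genome_mode import FilterThresholds, GeneIndex, _runs
from .models import AlignedPair, GeneModel, RetrocopyEvent

log = logging.getLogger(__name__)

MIN_CLUSTER_SPAN = 500
MAX_CLUSTER_SPAN = 50_000


@dataclass
class DeletionCluster:
    """A group of deletion-like pairs skipping the same intron set."""

    gene_id: str
    chrom: str
    introns: frozenset[int]          # transcription-order intron indices
    breakpoint_left: int             # max of member left-mate ends
    breakpoint_right: int            # min of member right-mate starts
    n_pairs: int
    samples_observed: set[str] = field(default_factory=set)
    pairs: list[AlignedPair] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.breakpoint_right - self.breakpoint_left

    @property
    def valid_span(self) -> bool:
        return MIN_CLUSTER_SPAN <= self.span < MAX_CLUSTER_SPAN

    def exons_involved(self, model: GeneModel) -> set[int]:
        out: set[int] = set()
        for i in self.introns:
            out |= {i, i + 1}
        return {i for i in out if 1 <= i <= model.n_exons}


def _deletion_signature(
    pair: AlignedPair, index: GeneIndex
) -> Optional[tuple[str, frozenset[int], int, int]]:
    """(gene, skipped introns, inner_left, inner_right) for a proper FR
    pair whose inner span fully contains >= 1 annotated intron."""
    if not pair.same_chrom:
        return None
    left, right = sorted(pair.mates, key=lambda m: m.pos)
    if left.strand != "+" or right.strand != "-":
        return None
    inner_lo, inner_hi = left.end, right.pos
    if inner_hi <= inner_lo:
        return None
    chrom = left.chrom
    for iv in index.trees.get(chrom, ()):
        if not (iv.begin <= min(left.pos, inner_lo)
                and max(right.end, inner_hi) <= iv.end):
            continue
        gene_id = iv.data
        model = index.primary_model(gene_id)
        skipped = {
            model.intron_index_at(s)
            for gi, (s, e) in enumerate(model.introns())
            if inner_lo <= s and e <= inner_hi
        }
        skipped.discard(None)
        if skipped:
            return gene_id, frozenset(skipped), inner_lo, inner_hi
    return None


def cluster_deletion_pairs(
    pairs: Iterable[AlignedPair],
    models: Iterable[GeneModel],
    thresholds: FilterThresholds = FilterThresholds(),
    index: Optional[GeneIndex] = None,
) -> list[DeletionCluster]:
    """Group deletion-like pairs by (gene, skipped intron set).

    Pairs skipping different introns of one gene form separate clusters;
    breakpoint uncertainty within a cluster is absorbed by keying on the
    intron set rather than raw coordinates.
    """
    index = index or GeneIndex(models)
    buckets: dict[tuple[str, frozenset[int]], DeletionCluster] = {}
    for pair in pairs:
        if min(pair.mate1.mapq, pair.mate2.mapq) < thresholds.min_mapq:
            continue
        sig = _deletion_signature(pair, index)
        if sig is None:
            continue
        gene_id, introns, lo, hi = sig
        key = (gene_id, introns)
        cl = buckets.get(key)
        if cl is None:
            chrom = index.span_by_gene[gene_id][0]
            cl = DeletionCluster(
                gene_id=gene_id, chrom=chrom, introns=introns,
                breakpoint_left=lo, breakpoint_right=hi, n_pairs=0,
            )
            buckets[key] = cl
        cl.breakpoint_left = max(cl.breakpoint_left, lo)
        cl.breakpoint_right = min(cl.breakpoint_right, hi)
        cl.n_pairs += 1
        cl.samples_observed.add(pair.sample)
        cl.pairs.append(pair)
    out = list(buckets.values())
    out.sort(key=lambda c: (c.chrom, c.breakpoint_left, c.gene_id))
    return out


def call_exome_candidates(
    clusters: Iterable[DeletionCluster],
    models: Iterable[GeneModel],
    thresholds: FilterThresholds = FilterThresholds(),
    index: Optional[GeneIndex] = None,
    sample: str = "tumour",
) -> list[RetrocopyEvent]:
    """Candidate = gene with >= 2 valid-span clusters involving >= 3 exons."""
    index = index or GeneIndex(models)
    by_gene: dict[str, list[DeletionCluster]] = defaultdict(list)
    for cl in clusters:
        if cl.valid_span:
            by_gene[cl.gene_id].append(cl)
    events = []
    for gene_id, cls in sorted(by_gene.items()):
        if len(cls) < 2:
            continue
        model = index.primary_model(gene_id)
        exons: set[int] = set()
        for cl in cls:
            exons |= cl.exons_involved(model)
        if len(exons) < thresholds.min_event_exons:
            continue
        events.append(
            RetrocopyEvent(
                source_gene=gene_id,
                sample=sample,
                exon_span=_runs(exons),
                full_length=(len(exons) == model.n_exons),
                supporting_pairs=sum(cl.n_pairs for cl in cls),
                n_exons_observed=len(exons),
                n_junctions_observed=len({i for cl in cls for i in cl.introns}),
                confidence="high",
            )
        )
    order = {gid: index.span_by_gene[gid] for gid in {e.source_gene for e in events}}
    events.sort(key=lambda ev: order[ev.source_gene])
    return events


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def germline_exclusion(
    candidate: RetrocopyEvent,
    clusters: list[DeletionCluster],
    normal_pairs: Iterable[AlignedPair],
    panel_pairs: Iterable[AlignedPair],
    models: Iterable[GeneModel],
    germline_deletions: Optional[list[tuple[str, int, int]]] = None,
    thresholds: FilterThresholds = FilterThresholds(),
    min_reciprocal: float = 0.8,
    index: Optional[GeneIndex] = None,
) -> tuple[Optional[RetrocopyEvent], Optional[str]]:
    """Reject a candidate with germline evidence.

    Any normal/panel pair supporting the same skipped-intron configuration
    rejects it (``germline_panel``); a skipped intron reciprocally
    overlapping (>= ``min_reciprocal``) a provided germline-deletion
    interval rejects it (``known_germline_deletion``).  When no deletion
    intervals are supplied that step is skipped with a warning.
    """
    index = index or GeneIndex(models)
    mine = [cl for cl in clusters if cl.gene_id == candidate.source_gene]
    my_sigs = {cl.introns for cl in mine}
    for pair in list(normal_pairs) + list(panel_pairs):
        sig = _deletion_signature(pair, index)
        if sig and sig[0] == candidate.source_gene and sig[1] in my_sigs:
            return None, "germline_panel"
    if germline_deletions is None:
        log.warning(
            "no germline-deletion intervals supplied; known-deletion "
            "exclusion skipped for %s", candidate.source_gene,
        )
    else:
        model = index.primary_model(candidate.source_gene)
        introns = model.introns()
        order = {model.intron_index_at(s): (s, e) for s, e in introns}
        for cl in mine:
            for i in cl.introns:
                iv = order.get(i)
                if iv is None:
                    continue
                for chrom, s, e in germline_deletions:
                    if chrom == model.chrom and reciprocal_overlap(iv, (s, e)) >= min_reciprocal:
                        return None, "known_germline_deletion"
    return candidate, None


def detect_exome(
    tumour_pairs: Iterable[AlignedPair],
    normal_pairs: Iterable[AlignedPair],
    panel_pairs: Iterable[AlignedPair],
    models: Iterable[GeneModel],
    thresholds: FilterThresholds = FilterThresholds(),
    germline_deletions: Optional[list[tuple[str, int, int]]] = None,
    sample: str = "tumour",
) -> tuple[list[RetrocopyEvent], list[tuple[RetrocopyEvent, str]]]:
    """Full exome-mode pipeline; returns (retained, rejected-with-reason).

    Retained plus rejected always partition the candidate list, and every
    rejection carries exactly one reason code.
    """
    models = list(models)
    index = GeneIndex(models)
    normal_pairs = list(normal_pairs)
    panel_pairs = list(panel_pairs)
    clusters = cluster_deletion_pairs(tumour_pairs, models, thresholds, index)
    candidates = call_exome_candidates(clusters, models, thresholds, index, sample)
    kept: list[RetrocopyEvent] = []
    rejected: list[tuple[RetrocopyEvent, str]] = []
    for cand in candidates:
        out, reason = germline_exclusion(
            cand, clusters, normal_pairs, panel_pairs, models,
            germline_deletions, thresholds, index=index,
        )
        if out is None:
            rejected.append((cand, reason))
        else:
            kept.append(out)
    return kept, rejected
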