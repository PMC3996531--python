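"""Base-pair insertion-site resolution and mechanistic feature calls.

Given a candidate retrocopy, discordant read pairs linking the source
gene to the insertion locus define a search window; soft-clipped reads
anchored in that window are realigned with an internal exact-seed (13 bp)
and-extend aligner to recover both junctions at single-base resolution.
The two breakpoints classify the site as a target-site duplication
(staggered endonuclease nicks duplicate the intervening reference on both
sides of the insert), a target-site deletion, or blunt; the polyA tail,
the TTTTAA endonuclease-motif window, twin-priming internal inversions
and junction microhomologies are then read off the clip sequences.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import (AlignedPair, GeneModel, InsertionJunction, Mate,
                     RetrocopyEvent, SITE_BLUNT, SITE_DELETION, SITE_TSD,
                     revcomp)

log = logging.getLogger(__name__)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SEED_SIZE = 13  # shared with the expressed-junction k-mer resolver


# ---------------------------------------------------------------------------
# Elementary sequence calls
# ---------------------------------------------------------------------------

def microhomology(left_seq: str, right_seq: str) -> int:
    """Length of the maximal identical overlap spanning a junction.

    The longest h such that the last h bases of ``left_seq`` equal the
    first h bases of ``right_seq``.
    """
    if not left_seq or not right_seq:
        return 0
    for h in range(min(len(left_seq), len(right_seq)), 0, -1):
        if left_seq[-h:] == right_seq[:h]:
            return h
    return 0


def motif_match_at(refseq: str, pos: int, strand: str) -> bool:
    """Fuzzy endonuclease-motif test at a 3' (polyA) junction.

    The polyA tail of a LINE-mediated insertion joins the genome between
    the TTTT and the AA of a TTTTAA (or very similar) motif.  On the
    insertion strand we require at least three T immediately 5' and at
    least one A immediately 3' of the break.
    """
    if strand == "+":
        return refseq[pos - 3:pos] == "TTT" and refseq[pos:pos + 1] == "A"
    return refseq[pos:pos + 3] == "AAA" and refseq[pos - 1:pos] == "T"


def motif_window(
    three_prime_bp: int, refseq: str, strand: str = "+", flank: int = 10
) -> tuple[str, bool, bool]:
    """Reference window around the polyA junction and motif flags.

    Returns (window, fuzzy_match, exact_consensus); the window is
    truncated at contig ends.
    """
    lo = max(0, three_prime_bp - flank)
    window = refseq[lo:three_prime_bp + flank]
    exact = (
        refseq[three_prime_bp - 4:three_prime_bp + 2] == "TTTTAA"
        if strand == "+"
        else refseq[three_prime_bp - 2:three_prime_bp + 4] == "TTAAAA"
    )
    return window, motif_match_at(refseq, three_prime_bp, strand), exact


def detect_polyA(
    tail_seqs: Iterable[str], min_run: int = 10, purity: float = 0.9
) -> int:
    """PolyA length from junction-abutting sequences.

    Each input must be oriented so that position 0 abuts the 3' junction
    and extends into the tail.  The call is the longest prefix ending in
    A whose mismatch count stays within ``1 - purity`` (at least one
    mismatch always tolerated) and that contains no two consecutive
    non-A bases; runs below ``min_run`` are reported as 0 (no tail).
    """
    tolerance = 1.0 - purity
    best = 0
    for seq in tail_seqs:
        mism = 0
        consec = 0
        run = 0
        for i, base in enumerate(seq):
            if base == "A":
                consec = 0
                if mism <= max(1, int(tolerance * (i + 1))):
                    run = i + 1
            else:
                mism += 1
                consec += 1
                if consec >= 2 or mism > max(1, int(tolerance * (i + 1))):
                    break
        best = max(best, run)
    return best if best >= min_run else 0


def classify_site(
    five_bp: int, three_bp: int, chrom: str, refseq: str, insert_strand: str = "+"
) -> InsertionJunction:
    """Classify an insertion site from its two resolved breakpoints.

    Breakpoints are given junction-wise (5' end of the insert, polyA end);
    internally the left-flank end ``a`` and right-flank resume ``b`` are
    compared: a > b means the segment [b, a) is duplicated on both sides
    of the insert (TSD); a < b means [a, b) was lost (target-site
    deletion); equality is a blunt join.
    """
    if insert_strand == "+":
        a, b = five_bp, three_bp
    else:
        a, b = three_bp, five_bp
    if a > b:
        site_class, tsd, dele = SITE_TSD, a - b, 0
        tsd_seq = refseq[b:a]
    elif a < b:
        site_class, tsd, dele, tsd_seq = SITE_DELETION, 0, b - a, ""
    else:
        site_class, tsd, dele, tsd_seq = SITE_BLUNT, 0, 0, ""
    window, fuzzy, exact = motif_window(three_bp, refseq, insert_strand)
    return InsertionJunction(
        chrom=chrom,
        five_prime_bp=five_bp,
        three_prime_bp=three_bp,
        site_class=site_class,
        tsd_length=tsd,
        deletion_length=dele,
        tsd_sequence=tsd_seq,
        motif_window=window,
        motif_match=fuzzy,
        exact_motif=exact,
        insert_strand=insert_strand,
    )


# ---------------------------------------------------------------------------
# Seed-and-extend clip realignment (BLAT stand-in)
# ---------------------------------------------------------------------------

@dataclass
class ClipObservation:
    """A soft-clipped read end anchored near a putative junction."""

    anchor_chrom: str
    anchor_pos: int            # junction-adjacent aligned base
    anchor_strand: str
    clip_side: str             # 'prefix' | 'suffix'
    clip_seq: str
    read_name: str
    anchor_start: int = 0
    anchor_end: int = 0

    def __post_init__(self) -> None:
        if not self.clip_seq:
            raise ValueError("empty clip sequence")


@dataclass
class ClipHit:
    target: str
    junction_pos: int          # target coordinate of the junction-adjacent base
    strand: str                # '+' if clip matches target forward
    extended: int              # bases matched
    reason: Optional[str] = None


def _extend_forward(q: str, target: str, pos: int) -> int:
    mism = 0
    i = 0
    while i < len(q) and pos + i < len(target):
        if q[i] != target[pos + i]:
            mism += 1
            if mism > 1 + i // 20:
                break
        i += 1
    return i


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def realign_clip(
    clip: ClipObservation | str,
    targets: dict[str, str],
    side: Optional[str] = None,
    seed_size: int = SEED_SIZE,
) -> Optional[ClipHit]:
    """Realign a soft-clipped sequence with an exact 13 bp seed and
    mismatch-tolerant extension (at most one mismatch per 20 bp).

    The seed is taken from the junction-proximal end of the clip (its
    start for suffix clips, its end for prefix clips); a unique placement
    across all targets and both strands is required — ambiguous hits
    return ``None``-like :class:`ClipHit` with ``reason='multimap'``.
    """
    if isinstance(clip, ClipObservation):
        seq, side = clip.clip_seq, clip.clip_side
    else:
        seq = clip
        if side is None:
            raise ValueError("side required when passing a bare sequence")
    side = "suffix" if side == "suffix" else "prefix"
    if len(seq) < seed_size:
        return ClipHit("", -1, "+", 0, reason="too_short")
    rseq = revcomp(seq)
    placements: list[tuple[str, int, str]] = []  # (target, junction_pos, strand)
    if side == "suffix":  # junction at clip start
        seed_f, seed_r = seq[:seed_size], rseq[-seed_size:]
        for name, tseq in targets.items():
            for p in _find_all(tseq, seed_f):
                placements.append((name, p, "+"))
            for p in _find_all(tseq, seed_r):
                placements.append((name, p + seed_size - 1, "-"))
    else:  # prefix clip: junction at clip end
        seed_f, seed_r = seq[-seed_size:], rseq[:seed_size]
        for name, tseq in targets.items():
            for p in _find_all(tseq, seed_f):
                placements.append((name, p + seed_size - 1, "+"))
            for p in _find_all(tseq, seed_r):
                placements.append((name, p, "-"))
    if not placements:
        return ClipHit("", -1, "+", 0, reason="no_seed")
    if len(placements) > 1:
        return ClipHit("", -1, "+", 0, reason="multimap")
    name, jpos, strand = placements[0]
    tseq = targets[name]
    # extend away from the junction
    if (side == "suffix" and strand == "+") or (side == "prefix" and strand == "-"):
        q = seq if strand == "+" else rseq
        start = jpos if side == "suffix" else jpos
        ext = _extend_forward(q, tseq, start)
    else:
        # extension runs leftwards in target coordinates
        q = seq[::-1] if strand == "+" else rseq[::-1]
        ext = _extend_forward(q, tseq[::-1], len(tseq) - 1 - jpos)
    if ext < seed_size:
        return ClipHit("", -1, "+", 0, reason="no_extension")
    return ClipHit(target=name, junction_pos=jpos, strand=strand, extended=ext)


# ---------------------------------------------------------------------------
# Evidence collection
# ---------------------------------------------------------------------------

def collect_insertion_evidence(
    model: GeneModel,
    pairs: Iterable[AlignedPair],
    gene_span: Optional[tuple[str, int, int]] = None,
    min_clip: int = SEED_SIZE,
    min_link_mapq: int = 10,
) -> tuple[list[Mate], list[ClipObservation]]:
    """Discordant links and soft-clip observations for one candidate.

    Links are pairs with one mate inside the source gene's exons and the
    other mapped elsewhere in the genome; the returned mates are the
    *away* mates (they sit at the insertion locus).  Clip observations
    are collected genome-wide here and filtered to the link window later.
    """
    chrom, glo, ghi = gene_span or (model.chrom, model.start, model.end)
    exonic = list(model.exons)

    def in_exons(m: Mate) -> bool:
        if m.chrom != model.chrom:
            return False
        return any(
            blo < e and s < bhi
            for blo, bhi in m.reference_blocks()
            for s, e in exonic
        )

    def in_gene(m: Mate) -> bool:
        return m.chrom == chrom and m.pos < ghi and m.end > glo

    links: list[Mate] = []
    clips: list[ClipObservation] = []
    for pair in pairs:
        m1, m2 = pair.mates
        for a, b in ((m1, m2), (m2, m1)):
            if in_exons(a) and b.is_mapped and not in_gene(b) and b.mapq >= min_link_mapq:
                links.append(b)
        for m in pair.mates:
            if not m.is_mapped:
                continue
            if len(m.clipped_prefix) >= min_clip:
                clips.append(ClipObservation(
                    anchor_chrom=m.chrom, anchor_pos=m.pos,
                    anchor_strand=m.strand, clip_side="prefix",
                    clip_seq=m.clipped_prefix, read_name=pair.read_name,
                    anchor_start=m.pos, anchor_end=m.end,
                ))
            if len(m.clipped_suffix) >= min_clip:
                clips.append(ClipObservation(
                    anchor_chrom=m.chrom, anchor_pos=m.end - 1,
                    anchor_strand=m.strand, clip_side="suffix",
                    clip_seq=m.clipped_suffix, read_name=pair.read_name,
                    anchor_start=m.pos, anchor_end=m.end,
                ))
    return links, clips


def _cluster_positions(
    mates: Sequence[Mate], max_gap: int = 3000
) -> list[tuple[str, int, int, int]]:
    """Cluster mate positions into (chrom, lo, hi, n) windows."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in mates:
        by_chrom[m.chrom].append((m.pos, m.end))
    clusters = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_lo, cur_hi, n = ivs[0][0], ivs[0][1], 1
        for lo, hi in ivs[1:]:
            if lo - cur_hi <= max_gap:
                cur_hi = max(cur_hi, hi)
                n += 1
            else:
                clusters.append((chrom, cur_lo, cur_hi, n))
                cur_lo, cur_hi, n = lo, hi, 1
        clusters.append((chrom, cur_lo, cur_hi, n))
    clusters.sort(key=lambda c: (-c[3], c[0], c[1]))
    return clusters


def _is_homopolymer(seq: str, base: str, purity: float = 0.9) -> bool:
    return len(seq) > 0 and seq.count(base) / len(seq) >= purity


# ---------------------------------------------------------------------------
# Twin-priming inversion detection
# ---------------------------------------------------------------------------

@dataclass
class InversionCall:
    inverted: bool
    internal_junction_t: Optional[int] = None   # transcript coordinate k
    truncation_t: Optional[int] = None
    micro_internal: Optional[int] = None
    no_duplication: bool = True
    complex_flag: bool = False
    n_reads: int = 0


def detect_inversion(
    model: GeneModel,
    cdna: str,
    clips: Iterable[ClipObservation],
) -> InversionCall:
    """Detect a twin-priming internal inversion from split evidence.

    Reads crossing the internal junction are anchored in one cDNA segment
    with a clip realigning to the transcript in the *opposite* orientation;
    the junction-adjacent transcript coordinates of the two sides are the
    truncation point and the internal breakpoint k (the two segments
    partition the cDNA suffix, so their coordinate ranges must not
    overlap — duplicated template would violate twin priming).
    """
    targets = {"cdna": cdna}
    votes: list[tuple[int, int]] = []  # (truncation t, internal junction k)
    anchor_ivs: list[tuple[int, int]] = []
    n_informative = 0
    for clip in clips:
        t_anchor = model.genome_to_transcript(clip.anchor_pos)
        if t_anchor is None:
            continue
        hit = realign_clip(clip, targets)
        if hit is None or hit.reason:
            continue
        # a clip crossing an ordinary splice or insert-edge junction matches
        # the transcript in the concordant orientation (equal to the gene
        # strand, independent of which way the read was sequenced); a clip
        # crossing a twin-priming junction matches in the opposite one
        if hit.strand == model.strand:
            continue
        n_informative += 1
        # the junction-adjacent transcript coordinates of the two sides are
        # the truncation point and the internal breakpoint k
        lo, hi = sorted((t_anchor, hit.junction_pos))
        votes.append((lo, hi))  # (truncation point, first base of downstream segment)
        ts = [model.genome_to_transcript(clip.anchor_start),
              model.genome_to_transcript(clip.anchor_end - 1)]
        ts = [t for t in ts if t is not None]
        if len(ts) == 2:
            anchor_ivs.append((min(ts), max(ts) + 1))
    if not votes:
        return InversionCall(inverted=False)
    (t0_hat, k_hat), _ = Counter(votes).most_common(1)[0]
    complex_flag = len(set(votes)) > 1
    # junction must not coincide with an annotated splice boundary
    boundaries = {ts for ts, _, _, _ in model.transcript_blocks()} - {0}
    if k_hat in boundaries:
        return InversionCall(inverted=False, complex_flag=True,
                             n_reads=n_informative)
    mh = microhomology(revcomp(cdna[t0_hat:k_hat]), cdna[k_hat:])
    # no duplicated template: evidence segments on the inverted (upstream)
    # side must stay below k, segments on the downstream side at or above it
    no_dup = all(
        hi <= k_hat or lo >= k_hat for lo, hi in anchor_ivs
    )
    return InversionCall(
        inverted=True,
        internal_junction_t=k_hat,
        truncation_t=t0_hat,
        micro_internal=mh,
        no_duplication=no_dup,
        complex_flag=complex_flag,
        n_reads=n_informative,
    )


# ---------------------------------------------------------------------------
# Full insertion-site mapping for a candidate event
# ---------------------------------------------------------------------------

def map_insertion_site(
    event: RetrocopyEvent,
    model: GeneModel,
    pairs: Iterable[AlignedPair],
    genome: dict[str, str],
    min_links: int = 2,
    window_pad: int = 300,
) -> RetrocopyEvent:
    """Resolve the insertion site of one candidate to base-pair precision.

    Fills ``event.junction`` (site class, TSD/deletion length and
    sequence, polyA length, motif window, microhomologies, inversion) or
    marks the event unmapped with a reason when no confidently mapped
    links exist (e.g. insertion into repetitive sequence).
    """
    pairs = list(pairs)
    cdna = model.spliced_sequence(genome[model.chrom])
    links, clips = collect_insertion_evidence(model, pairs)
    if not links:
        event.insertion_chrom = None
        event.notes = "unmapped:no_links"
        return event
    clusters = _cluster_positions(links)
    chrom, wlo, whi, n_links = clusters[0]
    if n_links < min_links:
        event.insertion_chrom = None
        event.notes = "unmapped:insufficient_links"
        return event
    wlo, whi = wlo - window_pad, whi + window_pad
    refseq = genome[chrom]
    targets = {"cdna": cdna}

    suffix_votes: Counter = Counter()   # candidate a = left flank end
    prefix_votes: Counter = Counter()
    a_clips: dict[int, list[ClipObservation]] = defaultdict(list)
    b_clips: dict[int, list[ClipObservation]] = defaultdict(list)
    a_kinds: list[tuple[str, Optional[ClipHit]]] = []
    b_kinds: list[tuple[str, Optional[ClipHit]]] = []
    inv_clips: list[ClipObservation] = []
    for clip in clips:
        in_window = (clip.anchor_chrom == chrom and wlo <= clip.anchor_pos <= whi)
        if model.genome_to_transcript(clip.anchor_pos) is not None:
            inv_clips.append(clip)
            continue
        if not in_window:
            continue
        hit = realign_clip(clip, targets)
        is_cdna = hit is not None and not hit.reason
        if clip.clip_side == "suffix":
            if _is_homopolymer(clip.clip_seq, "T"):
                a_kinds.append(("polyT", None))
            elif is_cdna:
                a_kinds.append(("cdna", hit))
            else:
                continue
            suffix_votes[clip.anchor_end] += 1
            a_clips[clip.anchor_end].append(clip)
        else:
            if _is_homopolymer(clip.clip_seq, "A"):
                b_kinds.append(("polyA", None))
            elif is_cdna:
                b_kinds.append(("cdna", hit))
            else:
                continue
            prefix_votes[clip.anchor_start] += 1
            b_clips[clip.anchor_start].append(clip)

    a_hat = suffix_votes.most_common(1)[0][0] if suffix_votes else None
    b_hat = prefix_votes.most_common(1)[0][0] if prefix_votes else None

    # Insert orientation relative to the reference plus strand.  The polyA
    # tail is the most reliable witness (an A-run prefix-clip means the
    # tail points left-to-right: '+'; a T-run suffix-clip means '-').
    # Without a tail, the junction whose clip realigns to the very 3' end
    # of the cDNA is the polyA-side junction; this stays valid for
    # twin-priming inversions, where raw hit strands are misleading.
    n_polyT = sum(1 for kind, _ in a_kinds if kind == "polyT")
    n_polyA = sum(1 for kind, _ in b_kinds if kind == "polyA")
    if n_polyA or n_polyT:
        orientation = "+" if n_polyA >= n_polyT else "-"
    else:
        L = len(cdna)
        b_at_end = any(k == "cdna" and h.junction_pos >= L - 3 for k, h in b_kinds)
        a_at_end = any(k == "cdna" and h.junction_pos >= L - 3 for k, h in a_kinds)
        if b_at_end != a_at_end:
            orientation = "+" if b_at_end else "-"
        else:
            strand_votes = Counter(
                h.strand for k, h in a_kinds + b_kinds if k == "cdna"
            )
            orientation = (strand_votes.most_common(1)[0][0]
                           if strand_votes else "+")

    inv = detect_inversion(model, cdna, inv_clips)

    if a_hat is None and b_hat is None:
        event.insertion_chrom = chrom
        event.insertion_point = (wlo + whi) // 2
        event.notes = "partial:no_clips"
        event.inverted = inv.inverted
        return event

    if a_hat is not None and b_hat is not None:
        five_bp = a_hat if orientation == "+" else b_hat
        three_bp = b_hat if orientation == "+" else a_hat
        junction = classify_site(five_bp, three_bp, chrom, refseq, orientation)
    else:
        resolved = a_hat if a_hat is not None else b_hat
        side_is_five = (a_hat is not None) == (orientation == "+")
        junction = InsertionJunction(
            chrom=chrom,
            five_prime_bp=resolved if side_is_five else None,
            three_prime_bp=resolved if not side_is_five else None,
            site_class=None,
            insert_strand=orientation,
        )
        event.notes = "partial:one_side"

    # polyA from tail clips at the polyA-side junction
    if orientation == "+":
        tail_clips = [c.clip_seq[::-1] for bs in b_clips.values() for c in bs]
    else:
        tail_clips = [c.clip_seq.translate(_COMPL)
                      for as_ in a_clips.values() for c in as_]
    junction.polyA_length = detect_polyA(tail_clips)

    # 5' microhomology between the flank and the insert start
    five_mh = None
    if orientation == "+" and a_hat is not None:
        cands = [microhomology(refseq[max(0, a_hat - 40):a_hat], c.clip_seq)
                 for c in a_clips.get(a_hat, [])]
        five_mh = max(cands, default=None)
    elif orientation == "-" and b_hat is not None:
        cands = [microhomology(revcomp(refseq[b_hat:b_hat + 40]),
                               revcomp(c.clip_seq))
                 for c in b_clips.get(b_hat, [])]
        five_mh = max(cands, default=None)
    junction.micro_5prime = five_mh
    junction.micro_internal = inv.micro_internal if inv.inverted else None

    event.insertion_chrom = chrom
    event.insertion_point = min(
        x for x in (junction.five_prime_bp, junction.three_prime_bp)
        if x is not None
    )
    event.junction = junction
    event.inverted = inv.inverted
    if inv.inverted and not inv.no_duplication:
        event.notes = (event.notes + ";" if event.notes else "") + "inversion_duplication"
    return event


# ---------------------------------------------------------------------------
# Expressed-junction resolution (RNA split-read k-mer algorithm)
# ---------------------------------------------------------------------------

@dataclass
class KmerHit:
    query_offset: int
    chrom: str
    pos: int                  # genome start of the extended fragment
    strand: str
    extended_length: int
    unique: bool = True


class GenomeKmerIndex:
    """Exact-match index of all genome k-mers (both strands considered)."""

    MULTI = ("*", -1)

    def __init__(self, genome: dict[str, str], k: int = SEED_SIZE) -> None:
        self.k = k
        self.genome = genome
        self.index: dict[str, tuple[str, int]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if kmer in self.index:
                    self.index[kmer] = self.MULTI
                else:
                    self.index[kmer] = (chrom, i)

    def locate(self, kmer: str) -> Optional[tuple[str, int, str]]:
        """Unique location of ``kmer`` (either strand), else None."""
        fwd = self.index.get(kmer)
        rev = self.index.get(revcomp(kmer))
        if fwd is not None and fwd != self.MULTI and rev is None:
            return (*fwd, "+")
        if rev is not None and rev != self.MULTI and fwd is None:
            return (*rev, "-")
        if fwd is not None and fwd != self.MULTI and rev == fwd:
            return None
        return None


def resolve_expressed_junction(
    reads: Iterable[str],
    transcript_seqs: dict[str, str],
    index: GenomeKmerIndex,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Split-read junction resolution for expressed retrocopies.

    Reads that map contiguously to a known transcript (either strand) are
    consumed; the remainder are shattered into 13-mers, each located at a
    unique genome position and extended one base at a time while the
    match (hence the unique placement) is maintained.  Adjacent uniquely
    extended fragments landing on different loci define the expressed
    breakpoint, returned as ((chrom, last base of left fragment),
    (chrom, first base of right fragment)).
    """
    junctions: list[tuple[tuple[str, int], tuple[str, int]]] = []
    k = index.k
    for read in reads:
        rc = revcomp(read)
        if any(read in t or rc in t for t in transcript_seqs.values()):
            continue
        frags: list[KmerHit] = []
        for off in range(0, len(read) - k + 1, k):
            loc = index.locate(read[off:off + k])
            if loc is None:
                continue
            chrom, pos, strand = loc
            seq = index.genome[chrom]
            # extend right then left, one base at a time, exact match
            right = off + k
            while right < len(read):
                if strand == "+":
                    nxt = pos + (right - off)
                    ok = nxt < len(seq) and seq[nxt] == read[right]
                else:
                    nxt = pos - (right - off - k) - 1
                    ok = nxt >= 0 and seq[nxt] == read[right].translate(_COMPL)
                if not ok:
                    break
                right += 1
            left = off
            while left > 0:
                if strand == "+":
                    nxt = pos - (off - left) - 1
                    ok = nxt >= 0 and seq[nxt] == read[left - 1]
                else:
                    nxt = pos + k + (off - left)
                    ok = nxt < len(seq) and seq[nxt] == read[left - 1].translate(_COMPL)
                if not ok:
                    break
                left -= 1
            g_start = pos - (off - left) if strand == "+" else pos - (right - off - k)
            frags.append(KmerHit(query_offset=left, chrom=chrom, pos=g_start,
                                 strand=strand, extended_length=right - left))
        # merge fragments on the same diagonal
        merged: list[KmerHit] = []
        for f in sorted(frags, key=lambda x: x.query_offset):
            if merged:
                m = merged[-1]
                same_locus = (
                    m.chrom == f.chrom and m.strand == f.strand
                    and (f.pos - m.pos == f.query_offset - m.query_offset
                         if f.strand == "+"
                         else m.pos - f.pos
                         == (f.query_offset + f.extended_length)
                         - (m.query_offset + m.extended_length))
                )
                if same_locus:
                    end = max(m.query_offset + m.extended_length,
                              f.query_offset + f.extended_length)
                    m.extended_length = end - m.query_offset
                    if f.strand == "-":
                        m.pos = min(m.pos, f.pos)
                    continue
            merged.append(f)
        for f1, f2 in zip(merged, merged[1:]):
            if f1.strand == "+":
                left_end = (f1.chrom, f1.pos + f1.extended_length - 1)
            else:
                left_end = (f1.chrom, f1.pos)
            if f2.strand == "+":
                right_start = (f2.chrom, f2.pos)
            else:
                right_start = (f2.chrom, f2.pos + f2.extended_length - 1)
            junctions.append((left_end, right_start))
    return junctions
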