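"""Synthetic-data generator for retrocopy insertion studies.

Builds a small random genome with spliced protein-coding genes, engineers
LINE-mediated retrocopy insertions carrying the mechanistic features seen
in somatic processed pseudogenes (5' truncation, polyA tails, 8-20 bp
target-site duplications or target-site deletions, twin-priming internal
inversions with junction microhomology, TTTTAA endonuclease-motif
insertion sites), and emits paired-end tumour/matched-normal/panel reads.

The generator bypasses external aligners: because every inserted base has
a known provenance, it computes each read's alignment to the *original*
reference itself, emitting soft-clips and discordant mate placements
exactly where a real aligner would put them, in both genome space and
transcriptome space.  The whole run is deterministic under the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from . import io as rio
from .breakpoints import microhomology, motif_match_at
from .models import (GeneModel, InsertionJunction, RetrocopyEvent, SITE_BLUNT,
                     SITE_DELETION, SITE_TSD, revcomp)

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulation; defaults are the study conditions.

    Feature probabilities default to the observed fractions in somatic
    pseudogene catalogues: 74% 5'-truncated, 21% internally inverted, and —
    among fully mapped sites — 67% TSD, 21% target-site deletion, the rest
    blunt; polyA tails present in 88%.  The fragment-length model emulates
    a tightly size-selected paired-end library (mean 220 bp, s.d. 20,
    truncated at +/-3.5 s.d.) whose upper tail lies below the 300 bp
    minimum-insert detection threshold.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 150_000
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (500, 3000)
    min_intergenic: int = 3000
    motif_spacing: int = 2000
    n_events: int = 8
    truncation_prob: float = 0.74
    truncation_model: str = "uniform"  # or "geometric" (3'-biased)
    inversion_prob: float = 0.21
    tsd_prob: float = 0.67
    site_deletion_prob: float = 0.21
    tsd_range: tuple[int, int] = (8, 20)
    site_deletion_range: tuple[int, int] = (100, 2000)
    polyA_prob: float = 0.88
    polyA_range: tuple[int, int] = (30, 80)
    motif_bias: float = 0.9
    read_length: int = 100
    fragment_mean: float = 220.0
    fragment_sd: float = 20.0
    fragment_truncate_sd: float = 3.5
    coverage: float = 30.0
    normal_coverage: float = 30.0
    panel_samples: int = 2
    panel_coverage: float = 5.0
    substitution_rate: float = 0.001

    def validate(self) -> None:
        for name in ("truncation_prob", "inversion_prob", "tsd_prob",
                     "site_deletion_prob", "polyA_prob", "motif_bias",
                     "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tsd_prob + self.site_deletion_prob > 1.0:
            raise ValueError("tsd_prob + site_deletion_prob > 1")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "tsd_range", "site_deletion_range", "polyA_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty range {name}=({lo}, {hi})")
        if self.n_events > self.n_genes:
            raise ValueError("n_events > n_genes (one event per source gene)")
        if self.coverage < 0 or self.read_length < 20:
            raise ValueError("bad read/coverage settings")


# ---------------------------------------------------------------------------
# Truth records and segment maps
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """A simulated event plus everything needed to reconstruct the insert."""

    event: RetrocopyEvent
    transcript_id: str
    t_trunc: int                      # transcript offset of the 5' truncation
    inversion_k: Optional[int]        # absolute transcript coord of internal junction
    orientation: str                  # insert strand relative to reference '+'
    chrom: str
    left_ref_end: int                 # a: reference coord where left flank ends
    right_ref_start: int              # b: reference coord where right flank resumes
    insert_seq: str                   # tumour plus-strand sequence of the insert
    cdna_seq: str                     # truncated cDNA, 5'->3'
    polyA_len: int
    site_class: str = SITE_BLUNT
    tsd_len: int = 0
    deletion_len: int = 0
    mh_5prime: int = 0
    mh_internal: Optional[int] = None

    def reconstruct_insert(self, full_cdna: str) -> str:
        """Rebuild the inserted sequence from its description (conservation)."""
        c = full_cdna[self.t_trunc:]
        if self.inversion_k is not None:
            k = self.inversion_k - self.t_trunc
            c = revcomp(c[:k]) + c[k:]
        c = c + "A" * self.polyA_len
        return c if self.orientation == "+" else revcomp(c)


@dataclass
class Segment:
    """A run of tumour-genome bases with a single provenance."""

    tum_start: int
    tum_end: int
    kind: str                         # 'genome' | 'cdna' | 'polyA'
    g_chrom: Optional[str] = None
    g_start: int = 0
    g_end: int = 0
    g_strand: str = "+"               # '+': tumour fwd text equals reference fwd
    transcript_id: Optional[str] = None
    t_lo: int = 0
    t_hi: int = 0
    t_strand: str = "+"
    t_run: int = -1                   # id of maximal transcript-contiguous run
    base: str = "A"                   # homopolymer base for polyA segments
    event_index: Optional[int] = None

    @property
    def length(self) -> int:
        return self.tum_end - self.tum_start


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Build reference chromosomes and gene models.

    Genes are placed left to right without overlap; intergenic sequence is
    seeded with TTTTAA/TTAAAA endonuclease motifs at roughly one per
    ``motif_spacing`` bp on top of chance occurrences.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {name: list(_random_dna(rng, config.chrom_length)) for name in chrom_names}

    models: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gid = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        cursor = config.min_intergenic
        for _ in range(n_here):
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0],
                                   config.exon_length[1] + 1, size=n_ex)
            in_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1, size=n_ex - 1)
            span = int(ex_lens.sum() + in_lens.sum())
            gap = int(rng.integers(config.min_intergenic,
                                   config.min_intergenic * 2))
            start = cursor + gap
            if start + span + config.min_intergenic > config.chrom_length:
                raise ValueError(
                    f"genes do not fit in chrom_length={config.chrom_length}; "
                    "reduce n_genes or gene sizes"
                )
            exons = []
            pos = start
            for j in range(n_ex):
                exons.append((pos, pos + int(ex_lens[j])))
                pos += int(ex_lens[j])
                if j < n_ex - 1:
                    pos += int(in_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            tlen = int(ex_lens.sum())
            cds_t = (min(50, tlen // 4), tlen - min(100, tlen // 4))
            g_coords = sorted(
                (GeneModel(  # throwaway model just to convert CDS bounds
                    gene_id="x", gene_name="x", transcript_id="x", chrom=chrom,
                    strand=strand, exons=tuple(exons),
                ).transcript_to_genome(t) for t in (cds_t[0], cds_t[1] - 1))
            )
            models.append(
                GeneModel(
                    gene_id=f"GENE{gid:03d}",
                    gene_name=f"GENE{gid:03d}",
                    transcript_id=f"TX{gid:03d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=g_coords[0],
                    cds_end=g_coords[1] + 1,
                )
            )
            cursor = pos
    # seed endonuclease motifs in intergenic space
    gene_ivs = {c: [(m.start, m.end) for m in models if m.chrom == c]
                for c in chrom_names}
    for chrom in chrom_names:
        n_mot = config.chrom_length // config.motif_spacing
        planted = 0
        attempts = 0
        while planted < n_mot and attempts < n_mot * 20:
            attempts += 1
            p = int(rng.integers(1000, config.chrom_length - 1000))
            if any(s - 10 <= p <= e + 10 for s, e in gene_ivs[chrom]):
                continue
            motif = "TTTTAA" if rng.random() < 0.5 else "TTAAAA"
            seqs[chrom][p:p + 6] = list(motif)
            planted += 1
    return {c: "".join(s) for c, s in seqs.items()}, models


# ---------------------------------------------------------------------------
# Retrocopy construction
# ---------------------------------------------------------------------------

def twin_prime(
    cdna: str,
    config: SimConfig,
    rng: np.random.Generator,
    avoid: tuple[int, ...] = (),
) -> tuple[str, int, int]:
    """Rearrange a cDNA by the twin-priming mechanism.

    Returns (rearranged sequence, internal breakpoint k, microhomology).
    The output is revcomp(cdna[:k]) + cdna[k:]: the two segments partition
    the cDNA with zero duplicated template bases.  k is drawn away from
    positions in ``avoid`` (splice boundaries) and redrawn until the
    internal junction shows 1-4 bp of microhomology.
    """
    n = len(cdna)
    if n < 80:
        raise ValueError("cDNA too short for twin priming")
    for _ in range(300):
        k = int(rng.integers(30, n - 30))
        if any(abs(k - a) < 10 for a in avoid):
            continue
        mh = microhomology(revcomp(cdna[:k]), cdna[k:])
        if 1 <= mh <= 4:
            return revcomp(cdna[:k]) + cdna[k:], k, mh
    raise RuntimeError("could not draw a twin-priming breakpoint with 1-4 bp "
                       "microhomology; sequence is pathological")


def _mh_vs_flank(ins: str, ref: str, a: int, b: int, orientation: str) -> int:
    """Microhomology at the 5' insertion point.

    For a '+' insert the 5' end abuts the left flank (suffix of ref[:a]);
    for a '-' insert it abuts the right flank read on the minus strand.
    """
    if orientation == "+":
        return microhomology(ref[max(0, a - 40):a], ins[:40])
    # minus: compare cDNA 5' prefix with revcomp of ref starting at b
    five = revcomp(ins)  # insert in its own 5'->3' orientation
    return microhomology(revcomp(ref[b:b + 40]), five[:40])


@dataclass
class _SitePicker:
    """Shared bookkeeping for drawing non-overlapping insertion sites."""

    seqs: dict[str, str]
    models: list[GeneModel]
    reserved: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.motifs = {
            "+": {c: find_all(s, "TTTTAA") for c, s in self.seqs.items()},
            "-": {c: find_all(s, "TTAAAA") for c, s in self.seqs.items()},
        }
        self.exons = {c: sorted(
            (s, e) for m in self.models if m.chrom == c for s, e in m.exons
        ) for c in self.seqs}
        self.gene_spans = {c: sorted(
            (m.start, m.end, m.gene_id) for m in self.models if m.chrom == c
        ) for c in self.seqs}

    def blocked(self, chrom: str, lo: int, hi: int, source_gene: str) -> bool:
        if lo < 1000 or hi > len(self.seqs[chrom]) - 1000:
            return True
        for s, e in self.exons[chrom]:
            if lo < e + 300 and s - 300 < hi:
                return True
        for s, e, gid in self.gene_spans[chrom]:
            if gid == source_gene and lo < e + 500 and s - 500 < hi:
                return True
        for c, s, e in self.reserved:
            if c == chrom and lo < e and s < hi:
                return True
        return False

    def reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.reserved.append((chrom, lo - 500, hi + 500))


def make_retrocopy(
    transcript: GeneModel,
    genome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    picker: Optional[_SitePicker] = None,
    models: Optional[list[GeneModel]] = None,
) -> TruthRecord:
    """Engineer one retrocopy insertion from ``transcript``.

    Draws 5' truncation, optional twin-priming inversion, polyA tail,
    junction class (TSD / target-site deletion / blunt) and an insertion
    point, biased towards TTTTAA endonuclease motifs, with the polyA end
    joined between the TTTT and the AA.
    """
    if transcript.n_exons < 3:
        raise ValueError(f"{transcript.transcript_id}: fewer than 3 exons")
    picker = picker or _SitePicker(seqs=genome, models=models or [transcript])
    full_cdna = transcript.spliced_sequence(genome[transcript.chrom])
    blocks = transcript.transcript_blocks()
    # 5' truncation leaving >= 3 exons represented (>= 2 splice junctions)
    max_t0 = blocks[-2][0] - 1  # must not reach the second-to-last exon
    t0 = 0
    if rng.random() < config.truncation_prob and max_t0 > 1:
        if config.truncation_model == "geometric":
            t0 = min(int(rng.geometric(2.0 / max_t0)), max_t0)
        else:
            t0 = int(rng.integers(1, max_t0 + 1))
    cdna = full_cdna[t0:]
    boundaries = tuple(ts - t0 for ts, _, _, _ in blocks if ts > t0)
    inversion_k = None
    mh_internal = None
    if rng.random() < config.inversion_prob:
        cdna, k, mh_internal = twin_prime(cdna, config, rng, avoid=boundaries)
        inversion_k = t0 + k
    polyA = 0
    if rng.random() < config.polyA_prob:
        polyA = int(rng.integers(config.polyA_range[0], config.polyA_range[1] + 1))
    seq_5to3 = cdna + "A" * polyA

    chrom_names = sorted(genome)
    for attempt in range(2000):
        orientation = "+" if rng.random() < 0.5 else "-"
        ins = seq_5to3 if orientation == "+" else revcomp(seq_5to3)
        u = rng.random()
        if u < config.tsd_prob:
            site_class = SITE_TSD
            tsd_len = int(rng.integers(config.tsd_range[0], config.tsd_range[1] + 1))
            del_len = 0
        elif u < config.tsd_prob + config.site_deletion_prob:
            site_class = SITE_DELETION
            tsd_len = 0
            del_len = int(rng.integers(config.site_deletion_range[0],
                                       config.site_deletion_range[1] + 1))
        else:
            site_class, tsd_len, del_len = SITE_BLUNT, 0, 0
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        ref = genome[chrom]
        if rng.random() < config.motif_bias and picker.motifs[orientation][chrom]:
            occ = picker.motifs[orientation][chrom]
            m = occ[int(rng.integers(0, len(occ)))]
            j3 = m + 4 if orientation == "+" else m + 2
        else:
            j3 = int(rng.integers(2000, len(ref) - 2000))
        # breakpoints: a = left flank end, b = right flank resume
        if orientation == "+":
            b = j3
            a = b + tsd_len if site_class == SITE_TSD else b - del_len
        else:
            a = j3
            b = a - tsd_len if site_class == SITE_TSD else a + del_len
        if site_class == SITE_BLUNT:
            a = b = j3
        lo, hi = min(a, b), max(a, b)
        if picker.blocked(chrom, lo - 50, hi + 50, transcript.gene_id):
            continue
        # reject sites where a chance base match would blur the junction
        if ref[a] == ins[0] or ref[b - 1] == ins[-1]:
            continue
        mh5 = _mh_vs_flank(ins, ref, a, b, orientation)
        if inversion_k is not None and not 1 <= mh5 <= 3:
            continue
        picker.reserve(chrom, lo, hi)
        break
    else:
        raise RuntimeError("failed to place insertion site")

    junction = InsertionJunction(
        chrom=chrom,
        five_prime_bp=a if orientation == "+" else b,
        three_prime_bp=j3,
        site_class=site_class,
        tsd_length=tsd_len,
        deletion_length=del_len,
        tsd_sequence=ref[lo:hi] if site_class == SITE_TSD else "",
        polyA_length=polyA,
        motif_window=ref[j3 - 10:j3 + 10],
        motif_match=motif_match_at(ref, j3, orientation),
        exact_motif=(
            ref[j3 - 4:j3 + 2] == "TTTTAA" if orientation == "+"
            else ref[j3 - 2:j3 + 4] == "TTAAAA"
        ),
        micro_5prime=mh5,
        micro_internal=mh_internal,
        insert_strand=orientation,
    )
    n_ex = transcript.n_exons
    idx_at = lambda t: next(i + 1 for i, (ts, te, _, _) in enumerate(blocks)
                            if ts <= t < te)
    if inversion_k is None:
        span = [(idx_at(t0), n_ex, "+")]
    else:
        span = [(idx_at(t0), idx_at(inversion_k - 1), "-"),
                (idx_at(inversion_k), n_ex, "+")]
    event = RetrocopyEvent(
        source_gene=transcript.gene_id,
        sample="tumour",
        exon_span=span,
        full_length=(t0 == 0),
        insertion_chrom=chrom,
        insertion_point=lo,
        junction=junction,
        inverted=inversion_k is not None,
    )
    return TruthRecord(
        event=event,
        transcript_id=transcript.transcript_id,
        t_trunc=t0,
        inversion_k=inversion_k,
        orientation=orientation,
        chrom=chrom,
        left_ref_end=a,
        right_ref_start=b,
        insert_seq=ins,
        cdna_seq=cdna,
        polyA_len=polyA,
        site_class=site_class,
        tsd_len=tsd_len,
        deletion_len=del_len,
        mh_5prime=mh5,
        mh_internal=mh_internal,
    )


# ---------------------------------------------------------------------------
# Tumour genome assembly
# ---------------------------------------------------------------------------

def _insert_segments(
    model: GeneModel, truth: TruthRecord
) -> list[dict]:
    """Provenance pieces of one insert, in tumour plus-strand order."""
    L = model.transcript_length
    t0, k_abs = truth.t_trunc, truth.inversion_k
    runs = ([(t0, L, "+")] if k_abs is None
            else [(t0, k_abs, "-"), (k_abs, L, "+")])
    pieces: list[dict] = []
    for lo, hi, orient in runs:
        blocks = model.transcript_blocks_in_range(lo, hi)
        if orient == "-":
            blocks = blocks[::-1]
        for tl, th, gs, ge in blocks:
            g_strand = model.strand if orient == "+" else _flip(model.strand)
            pieces.append(dict(kind="cdna", length=th - tl,
                               g_chrom=model.chrom, g_start=gs, g_end=ge,
                               g_strand=g_strand, t_lo=tl, t_hi=th,
                               t_strand=orient))
    if truth.polyA_len:
        pieces.append(dict(kind="polyA", length=truth.polyA_len, base="A"))
    if truth.orientation == "-":
        flipped = []
        for p in reversed(pieces):
            q = dict(p)
            if q["kind"] == "cdna":
                q["g_strand"] = _flip(q["g_strand"])
                q["t_strand"] = _flip(q["t_strand"])
            else:
                q["base"] = "T"
            flipped.append(q)
        pieces = flipped
    return pieces


def reference_segments(ref_seqs: dict[str, str]) -> dict[str, list[Segment]]:
    """Trivial segment map for an unmodified genome (normal/panel samples)."""
    return {
        c: [Segment(tum_start=0, tum_end=len(s), kind="genome", g_chrom=c,
                    g_start=0, g_end=len(s), g_strand="+")]
        for c, s in ref_seqs.items()
    }


def apply_insertions(
    ref_seqs: dict[str, str],
    truths: list[TruthRecord],
    models: list[GeneModel],
) -> tuple[dict[str, str], dict[str, list[Segment]]]:
    """Build the tumour genome and its provenance segment map.

    Tumour length = reference + sum(insert length + TSD - deletion) per
    chromosome; overlapping target sites are an error.
    """
    by_tid = {m.transcript_id: m for m in models}
    tumour: dict[str, str] = {}
    segmap: dict[str, list[Segment]] = {}
    run_counter = 0
    for chrom, ref in ref_seqs.items():
        evs = sorted(
            (t for t in truths if t.chrom == chrom),
            key=lambda t: min(t.left_ref_end, t.right_ref_start),
        )
        for e1, e2 in zip(evs, evs[1:]):
            if max(e1.left_ref_end, e1.right_ref_start) > min(
                e2.left_ref_end, e2.right_ref_start
            ):
                raise ValueError(
                    f"overlapping target sites on {chrom}: "
                    f"{e1.event.source_gene} and {e2.event.source_gene}"
                )
        parts: list[str] = []
        segs: list[Segment] = []
        ref_cursor = 0
        tum_cursor = 0
        for t in evs:
            a, b = t.left_ref_end, t.right_ref_start
            flank = ref[ref_cursor:a]
            parts.append(flank)
            segs.append(Segment(tum_start=tum_cursor, tum_end=tum_cursor + len(flank),
                                kind="genome", g_chrom=chrom, g_start=ref_cursor,
                                g_end=a, g_strand="+"))
            tum_cursor += len(flank)
            parts.append(t.insert_seq)
            ev_index = truths.index(t)
            prev = None
            for p in _insert_segments(by_tid[t.transcript_id], t):
                seg = Segment(
                    tum_start=tum_cursor, tum_end=tum_cursor + p["length"],
                    kind=p["kind"], event_index=ev_index,
                )
                if p["kind"] == "cdna":
                    seg.g_chrom = p["g_chrom"]
                    seg.g_start, seg.g_end = p["g_start"], p["g_end"]
                    seg.g_strand = p["g_strand"]
                    seg.transcript_id = t.transcript_id
                    seg.t_lo, seg.t_hi = p["t_lo"], p["t_hi"]
                    seg.t_strand = p["t_strand"]
                    contiguous = (
                        prev is not None and prev.kind == "cdna"
                        and prev.t_strand == seg.t_strand
                        and (prev.t_hi == seg.t_lo if seg.t_strand == "+"
                             else prev.t_lo == seg.t_hi)
                    )
                    if not contiguous:
                        run_counter += 1
                    seg.t_run = run_counter
                else:
                    seg.base = p["base"]
                segs.append(seg)
                prev = seg
                tum_cursor += p["length"]
            ref_cursor = b
        tail = ref[ref_cursor:]
        parts.append(tail)
        segs.append(Segment(tum_start=tum_cursor, tum_end=tum_cursor + len(tail),
                            kind="genome", g_chrom=chrom, g_start=ref_cursor,
                            g_end=len(ref), g_strand="+"))
        tumour[chrom] = "".join(parts)
        segmap[chrom] = [s for s in segs if s.length > 0]
        # conservation: segment-reconstructed sequence equals the built one
        rebuilt = []
        for s in segmap[chrom]:
            if s.kind == "genome":
                rebuilt.append(ref_seqs[s.g_chrom][s.g_start:s.g_end])
            elif s.kind == "polyA":
                rebuilt.append(s.base * s.length)
            else:
                piece = ref_seqs[s.g_chrom][s.g_start:s.g_end]
                rebuilt.append(piece if s.g_strand == "+" else revcomp(piece))
        assert "".join(rebuilt) == tumour[chrom], "segment map inconsistent"
    return tumour, segmap


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _make_rec(
    header: pysam.AlignmentHeader, name: str, read1: bool,
    ref: Optional[str], pos: int, reverse: bool,
    cigar: Optional[list[tuple[str, int]]], seq: str, mapq: int,
    mate_ref: Optional[str], mate_pos: int, mate_reverse: bool,
    mate_unmapped: bool,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = seq
    rec.is_paired = True
    rec.is_read1 = read1
    rec.is_read2 = not read1
    if ref is None:
        rec.is_unmapped = True
        rec.mapping_quality = 0
        if mate_ref is not None:
            rec.reference_name = mate_ref
            rec.reference_start = mate_pos
    else:
        rec.reference_name = ref
        rec.reference_start = pos
        rec.is_reverse = reverse
        rec.mapping_quality = mapq
        rec.cigarstring = "".join(f"{n}{op}" for op, n in cigar)
    if mate_unmapped:
        rec.mate_is_unmapped = True
        if ref is not None:
            rec.next_reference_name = ref
            rec.next_reference_start = pos
    elif mate_ref is not None:
        rec.next_reference_name = mate_ref
        rec.next_reference_start = mate_pos
        rec.mate_is_reverse = mate_reverse
    return rec


class _ExonIndex:
    """Locate reads fully contained in an annotated exon."""

    def __init__(self, models: list[GeneModel]) -> None:
        self.by_chrom: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for m in models:
            for s, e in m.exons:
                self.by_chrom.setdefault(m.chrom, []).append((s, e, m))
        for c in self.by_chrom:
            self.by_chrom[c].sort(key=lambda x: x[0])

    def containing(self, chrom: str, lo: int, hi: int) -> Optional[tuple[int, int, GeneModel]]:
        for s, e, m in self.by_chrom.get(chrom, []):
            if s <= lo and hi <= e:
                return (s, e, m)
            if s > lo:
                break
        return None


def generate_reads(
    genome: dict[str, str],
    segmap: dict[str, list[Segment]],
    models: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
    sample: str,
    coverage: float,
    out_dir: str | Path,
    write_fastq: bool = False,
) -> dict[str, int]:
    """Sample paired-end fragments and emit genome- and transcriptome-space SAM.

    Alignments are computed from provenance, not by an aligner: reads
    crossing an insertion junction appear with soft-clips, reads wholly
    inside the retrocopy map to the source transcript (and hence, after
    projection, discordantly in genome space), polyA-only reads are
    unmapped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_lengths = {m.chrom: len(genome[m.chrom]) for m in models}
    for c, s in genome.items():
        ref_lengths.setdefault(c, len(s))
    # reference (not tumour) lengths for the genome-space header
    g_lengths: dict[str, int] = {}
    for c, segs in segmap.items():
        g_lengths[c] = max(s.g_end for s in segs if s.kind == "genome")
    g_header = rio.sam_header(g_lengths)
    t_header = rio.sam_header({m.transcript_id: m.transcript_length for m in models})
    exon_index = _ExonIndex(models)

    starts = {c: [s.tum_start for s in segs] for c, segs in segmap.items()}
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(coverage * total / (2 * config.read_length)))
    frag_lo = max(config.read_length + 10,
                  config.fragment_mean - config.fragment_truncate_sd * config.fragment_sd)
    frag_hi = config.fragment_mean + config.fragment_truncate_sd * config.fragment_sd

    import bisect

    def overlapping(chrom: str, lo: int, hi: int) -> list[Segment]:
        segs = segmap[chrom]
        i = bisect.bisect_right(starts[chrom], lo) - 1
        out = []
        while i < len(segs) and segs[i].tum_start < hi:
            if segs[i].tum_end > lo:
                out.append(segs[i])
            i += 1
        return out

    def genome_view(chrom: str, s: int, e: int, d: str, seq: str):
        """(ref, pos, reverse, cigar, stored_seq) for the primary genome alignment."""
        segs = [x for x in overlapping(chrom, s, e) if x.kind != "polyA"]
        if not segs:
            return None
        anchor = max(segs, key=lambda x: min(e, x.tum_end) - max(s, x.tum_start))
        os_, oe = max(s, anchor.tum_start), min(e, anchor.tum_end)
        pre, post = os_ - s, e - oe
        if anchor.g_strand == "+":
            pos = anchor.g_start + (os_ - anchor.tum_start)
            cigar = [("S", pre)] if pre else []
            cigar += [("M", oe - os_)]
            cigar += [("S", post)] if post else []
            return (anchor.g_chrom, pos, d == "-", cigar, seq)
        pos = anchor.g_end - (oe - anchor.tum_start)
        cigar = [("S", post)] if post else []
        cigar += [("M", oe - os_)]
        cigar += [("S", pre)] if pre else []
        return (anchor.g_chrom, pos, d == "+", cigar, revcomp(seq))

    by_tid = {m.transcript_id: m for m in models}

    def transcript_view(chrom: str, s: int, e: int, d: str, seq: str):
        """Full-length transcript-space alignment, or None."""
        segs = overlapping(chrom, s, e)
        if all(x.kind == "cdna" for x in segs) and len({x.t_run for x in segs}) == 1:
            first = segs[0]
            if first.t_strand == "+":
                t0 = first.t_lo + (s - first.tum_start)
                return (first.transcript_id, t0, d == "-", [("M", e - s)], seq)
            last = segs[-1]
            t_end = first.t_hi - (s - first.tum_start)
            t0 = t_end - (e - s)
            return (first.transcript_id, t0, d == "+", [("M", e - s)], revcomp(seq))
        if len(segs) == 1 and segs[0].kind == "genome":
            g = segs[0]
            glo = g.g_start + (s - g.tum_start)
            hit = exon_index.containing(g.g_chrom, glo, glo + (e - s))
            if hit is None:
                return None
            _, _, m = hit
            ts = [m.genome_to_transcript(glo), m.genome_to_transcript(glo + (e - s) - 1)]
            t0 = min(ts)
            if m.strand == "+":
                return (m.transcript_id, t0, d == "-", [("M", e - s)], seq)
            return (m.transcript_id, t0, d == "+", [("M", e - s)], revcomp(seq))
        return None

    n_written = n_t_pairs = 0
    fq1 = fq2 = None
    if write_fastq:
        fq1 = open(out_dir / f"{sample}.r1.fastq", "w")
        fq2 = open(out_dir / f"{sample}.r2.fastq", "w")
    with pysam.AlignmentFile(str(out_dir / f"{sample}.genome.sam"), "wh",
                             header=g_header) as gout, \
         pysam.AlignmentFile(str(out_dir / f"{sample}.transcriptome.sam"), "wh",
                             header=t_header) as tout:
        probs = lengths / total
        chrom_draws = rng.choice(len(chroms), size=n_pairs, p=probs)
        frags = np.clip(rng.normal(config.fragment_mean, config.fragment_sd,
                                   size=n_pairs), frag_lo, frag_hi).astype(int)
        for i in range(n_pairs):
            chrom = chroms[chrom_draws[i]]
            L = len(genome[chrom])
            frag = int(frags[i])
            if frag >= L:
                continue
            s0 = int(rng.integers(0, L - frag))
            rl = config.read_length
            intervals = [(s0, s0 + rl, "+"), (s0 + frag - rl, s0 + frag, "-")]
            name = f"{sample}.{chrom}.{i}"
            texts = []
            for (s, e, d) in intervals:
                txt = genome[chrom][s:e]
                if config.substitution_rate > 0:
                    nerr = rng.binomial(rl, config.substitution_rate)
                    if nerr:
                        txt = list(txt)
                        for p in rng.integers(0, rl, size=nerr):
                            txt[p] = "ACGT"[int(rng.integers(0, 4))]
                        txt = "".join(txt)
                texts.append(txt)
            views = [genome_view(chrom, s, e, d, txt)
                     for (s, e, d), txt in zip(intervals, texts)]
            recs = []
            for j, ((s, e, d), view) in enumerate(zip(intervals, views)):
                other = views[1 - j]
                m_ref = other[0] if other else None
                m_pos = other[1] if other else 0
                m_rev = other[2] if other else False
                if view is None:
                    recs.append(_make_rec(g_header, name, j == 0, None, 0, False,
                                          None, texts[j], 0, m_ref, m_pos, m_rev,
                                          False))
                else:
                    recs.append(_make_rec(g_header, name, j == 0, view[0], view[1],
                                          view[2], view[3], view[4], 60,
                                          m_ref, m_pos, m_rev, other is None))
            for rec in recs:
                gout.write(rec)
            n_written += 1
            tviews = [transcript_view(chrom, s, e, d, txt)
                      for (s, e, d), txt in zip(intervals, texts)]
            if (tviews[0] is not None and tviews[1] is not None
                    and tviews[0][0] == tviews[1][0]):
                for j, view in enumerate(tviews):
                    other = tviews[1 - j]
                    tout.write(_make_rec(t_header, name, j == 0, view[0], view[1],
                                         view[2], view[3], view[4], 60,
                                         other[0], other[1], other[2], False))
                n_t_pairs += 1
            if write_fastq:
                q = "I" * rl
                fq1.write(f"@{name}\n{texts[0]}\n+\n{q}\n")
                fq2.write(f"@{name}\n{revcomp(texts[1])}\n+\n{q}\n")
    if write_fastq:
        fq1.close()
        fq2.close()
    return {"pairs": n_written, "transcriptome_pairs": n_t_pairs}


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    out_dir: Path
    reference: dict[str, str]
    tumour_genome: dict[str, str]
    models: list[GeneModel]
    truths: list[TruthRecord]
    segmap: dict[str, list[Segment]]
    samples: dict[str, dict[str, int]]

    @property
    def reference_fasta(self) -> Path:
        return self.out_dir / "reference.fa"

    @property
    def gtf(self) -> Path:
        return self.out_dir / "genes.gtf"

    def sam(self, sample: str, space: str = "genome") -> Path:
        return self.out_dir / f"{sample}.{space}.sam"

    @property
    def panel_names(self) -> list[str]:
        return [s for s in self.samples if s.startswith("panel")]


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Run the full generator: genome, events, and all samples' reads."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    g_rng, e_rng, r_rng = master.spawn(3)

    reference, models = make_genome(config, g_rng)
    rio.write_fasta(reference, out_dir / "reference.fa")
    rio.write_gene_models(models, out_dir / "genes.gtf")

    eligible = [m for m in models if m.n_exons >= 3]
    order = e_rng.permutation(len(eligible))
    sources = [eligible[i] for i in order[: config.n_events]]
    picker = _SitePicker(seqs=reference, models=models)
    truths = [
        make_retrocopy(src, reference, config, e_rng, picker=picker, models=models)
        for src in sources
    ]
    tumour, segmap = apply_insertions(reference, truths, models)

    samples: dict[str, dict[str, int]] = {}
    sample_rngs = r_rng.spawn(2 + config.panel_samples)
    samples["tumour"] = generate_reads(
        tumour, segmap, models, config, sample_rngs[0], "tumour",
        config.coverage, out_dir, write_fastq=True,
    )
    ref_segs = reference_segments(reference)
    samples["normal"] = generate_reads(
        reference, ref_segs, models, config, sample_rngs[1], "normal",
        config.normal_coverage, out_dir,
    )
    for i in range(config.panel_samples):
        name = f"panel{i + 1}"
        samples[name] = generate_reads(
            reference, ref_segs, models, config, sample_rngs[2 + i], name,
            config.panel_coverage, out_dir,
        )

    truth_df = rio.events_to_frame([t.event for t in truths])
    truth_df["transcript_id"] = [t.transcript_id for t in truths]
    truth_df["t_trunc"] = [t.t_trunc for t in truths]
    truth_df["inversion_k"] = [t.inversion_k for t in truths]
    truth_df["orientation"] = [t.orientation for t in truths]
    truth_df["left_ref_end"] = [t.left_ref_end for t in truths]
    truth_df["right_ref_start"] = [t.right_ref_start for t in truths]
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return SimResult(
        config=config, out_dir=out_dir, reference=reference,
        tumour_genome=tumour, models=models, truths=truths, segmap=segmap,
        samples=samples,
    )
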