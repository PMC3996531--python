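"""Core domain types for retrocopy (processed-pseudogene) analysis.

Coordinate convention: every coordinate held in memory is 0-based,
half-open.  Readers convert from the 1-based inclusive conventions of
GTF/SAM at the boundary; writers convert back.  Exon *indices* are
1-based and follow transcription direction (exon 1 is the 5'-most exon
on the coding strand), matching the way retrocopy catalogues describe
exon content (e.g. "KTN1 11-14; 44").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A transcript: ordered exons on a named reference sequence.

    ``exons`` are non-overlapping (start, end) intervals sorted by genomic
    coordinate regardless of strand.  CDS bounds are genomic coordinates or
    ``None`` for non-coding transcripts.
    """

    gene_id: str
    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = end

    # -- basic geometry ----------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])

    def exon(self, index: int) -> tuple[int, int]:
        """Genomic interval of 1-based exon ``index`` in transcription order."""
        order = self.exons_in_transcription_order()
        if not 1 <= index <= len(order):
            raise IndexError(f"exon {index} of {len(order)}")
        return order[index - 1]

    def exon_index_at(self, gpos: int) -> Optional[int]:
        """1-based transcription-order exon index containing ``gpos``, else None."""
        for i, (s, e) in enumerate(self.exons_in_transcription_order(), start=1):
            if s <= gpos < e:
                return i
        return None

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals, sorted by genomic coordinate."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def intron_index_at(self, gpos: int) -> Optional[int]:
        """1-based transcription-order intron index containing ``gpos``."""
        for gi, (s, e) in enumerate(self.introns()):
            if s <= gpos < e:
                # genomic intron gi sits after genomic exon gi
                if self.strand == "+":
                    return gi + 1
                return len(self.exons) - 1 - gi
        return None

    def splice_junctions(self) -> set[tuple[int, int]]:
        """Genomic (donor_end, acceptor_start) pairs of adjacent exons."""
        return {
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        }

    # -- transcript <-> genome mapping ------------------------------------
    def transcript_blocks(self) -> list[tuple[int, int, int, int]]:
        """(t_start, t_end, g_start, g_end) per exon, in transcription order.

        For minus-strand transcripts, transcript coordinate ``t`` inside a
        block maps to genome position ``g_end - 1 - (t - t_start)``.
        """
        blocks = []
        t = 0
        for s, e in self.exons_in_transcription_order():
            blocks.append((t, t + (e - s), s, e))
            t += e - s
        return blocks

    def transcript_to_genome(self, tpos: int) -> int:
        if not 0 <= tpos < self.transcript_length:
            raise ValueError(f"transcript position {tpos} outside transcript")
        for ts, te, gs, ge in self.transcript_blocks():
            if ts <= tpos < te:
                if self.strand == "+":
                    return gs + (tpos - ts)
                return ge - 1 - (tpos - ts)
        raise AssertionError("unreachable")

    def genome_to_transcript(self, gpos: int) -> Optional[int]:
        for ts, te, gs, ge in self.transcript_blocks():
            if gs <= gpos < ge:
                if self.strand == "+":
                    return ts + (gpos - gs)
                return ts + (ge - 1 - gpos)
        return None

    def transcript_interval_to_genome(self, t_start: int, t_end: int) -> list[tuple[int, int, str]]:
        """Project transcript interval [t_start, t_end) to genomic blocks.

        Returns (g_start, g_end, strand) triples in *transcription* order;
        for minus-strand transcripts genomic coordinates descend.
        """
        if not 0 <= t_start < t_end <= self.transcript_length:
            raise ValueError(f"bad transcript interval [{t_start}, {t_end})")
        out = []
        for ts, te, gs, ge in self.transcript_blocks():
            lo, hi = max(t_start, ts), min(t_end, te)
            if lo >= hi:
                continue
            if self.strand == "+":
                out.append((gs + (lo - ts), gs + (hi - ts), "+"))
            else:
                out.append((ge - (hi - ts), ge - (lo - ts), "-"))
        return out

    def transcript_blocks_in_range(
        self, t_start: int, t_end: int
    ) -> list[tuple[int, int, int, int]]:
        """(t_lo, t_hi, g_start, g_end) per exon block overlapping [t_start, t_end).

        Blocks are returned in transcription order; genomic intervals are
        always (start, end) with start < end regardless of strand.
        """
        if not 0 <= t_start < t_end <= self.transcript_length:
            raise ValueError(f"bad transcript interval [{t_start}, {t_end})")
        out = []
        for ts, te, gs, ge in self.transcript_blocks():
            lo, hi = max(t_start, ts), min(t_end, te)
            if lo >= hi:
                continue
            if self.strand == "+":
                out.append((lo, hi, gs + (lo - ts), gs + (hi - ts)))
            else:
                out.append((lo, hi, ge - (hi - ts), ge - (lo - ts)))
        return out

    def spliced_sequence(self, chrom_seq: str) -> str:
        """cDNA sequence (5'->3' on the coding strand)."""
        parts = [chrom_seq[s:e] for s, e in self.exons]
        cdna = "".join(parts)
        return cdna if self.strand == "+" else revcomp(cdna)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

QUERY_OPS = set("MIS=X")
REF_OPS = set("MDN=X")


@dataclass
class Mate:
    """One aligned read of a pair.

    ``cigar_ops`` is a list of (op, length) with SAM operation letters.
    ``pos`` is the 0-based leftmost reference coordinate (ignored when
    unmapped).  ``seq`` is the read sequence as stored in the alignment
    (reference orientation for mapped reads).
    """

    chrom: Optional[str]
    pos: int
    strand: str
    cigar_ops: list[tuple[str, int]]
    mapq: int
    seq: str

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        qlen = sum(n for op, n in self.cigar_ops if op in QUERY_OPS)
        if self.cigar_ops and self.seq and qlen != len(self.seq):
            raise ValueError(
                f"CIGAR query length {qlen} != read length {len(self.seq)}"
            )

    @property
    def is_mapped(self) -> bool:
        return self.chrom is not None

    @property
    def end(self) -> int:
        """Rightmost reference coordinate (half-open)."""
        return self.pos + sum(n for op, n in self.cigar_ops if op in REF_OPS)

    @property
    def clipped_prefix(self) -> str:
        if self.cigar_ops and self.cigar_ops[0][0] == "S":
            return self.seq[: self.cigar_ops[0][1]]
        return ""

    @property
    def clipped_suffix(self) -> str:
        if self.cigar_ops and self.cigar_ops[-1][0] == "S":
            return self.seq[len(self.seq) - self.cigar_ops[-1][1]:]
        return ""

    @property
    def n_splits(self) -> int:
        """Number of N (intron-skip) operations in the CIGAR."""
        return sum(1 for op, _ in self.cigar_ops if op == "N")

    @property
    def match_blocks(self) -> list[int]:
        return [n for op, n in self.cigar_ops if op in "M=X"]

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Contiguous aligned reference intervals (split at N/D)."""
        blocks = []
        ref = self.pos
        cur_start = None
        for op, n in self.cigar_ops:
            if op in "M=X":
                if cur_start is None:
                    cur_start = ref
                ref += n
            elif op in "DN":
                if cur_start is not None:
                    blocks.append((cur_start, ref))
                    cur_start = None
                ref += n
        if cur_start is not None:
            blocks.append((cur_start, ref))
        return blocks

    def skipped_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals covered by N operations."""
        out = []
        ref = self.pos
        for op, n in self.cigar_ops:
            if op == "N":
                out.append((ref, ref + n))
            if op in REF_OPS:
                ref += n
        return out


@dataclass
class AlignedPair:
    read_name: str
    sample: str
    mate1: Mate
    mate2: Mate

    @property
    def mates(self) -> tuple[Mate, Mate]:
        return (self.mate1, self.mate2)

    @property
    def same_chrom(self) -> bool:
        return (
            self.mate1.is_mapped
            and self.mate2.is_mapped
            and self.mate1.chrom == self.mate2.chrom
        )


# ---------------------------------------------------------------------------
# Events and junctions
# ---------------------------------------------------------------------------

SITE_TSD = "TSD"
SITE_DELETION = "target_site_deletion"
SITE_BLUNT = "blunt"


@dataclass
class InsertionJunction:
    """Base-pair-resolved insertion site with mechanistic features.

    ``five_prime_bp`` / ``three_prime_bp`` are reference coordinates of the
    junctions adjoining the 5' end of the retrocopy and its polyA (3') end.
    A TSD means the two breakpoints overlap (the intervening reference
    segment is duplicated on both sides of the insert); a target-site
    deletion means they leave a gap; blunt means they coincide.
    """

    chrom: str
    five_prime_bp: Optional[int]
    three_prime_bp: Optional[int]
    site_class: Optional[str] = None
    tsd_length: int = 0
    deletion_length: int = 0
    tsd_sequence: str = ""
    polyA_length: int = 0
    motif_window: str = ""
    motif_match: bool = False
    exact_motif: bool = False
    micro_5prime: Optional[int] = None
    micro_internal: Optional[int] = None
    insert_strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.site_class == SITE_TSD and self.tsd_length < 1:
            raise ValueError("TSD requires tsd_length >= 1")
        if self.site_class == SITE_BLUNT and (self.tsd_length or self.deletion_length):
            raise ValueError("blunt site cannot carry TSD/deletion lengths")
        if self.tsd_sequence and len(self.tsd_sequence) != self.tsd_length:
            raise ValueError("tsd_sequence length != tsd_length")

    @property
    def fully_mapped(self) -> bool:
        return self.five_prime_bp is not None and self.three_prime_bp is not None


@dataclass
class RetrocopyEvent:
    """A candidate or simulated processed pseudogene."""

    source_gene: str
    sample: str
    exon_span: list[tuple[int, int, str]] = field(default_factory=list)
    full_length: bool = False
    insertion_chrom: Optional[str] = None
    insertion_point: Optional[int] = None
    junction: Optional[InsertionJunction] = None
    inverted: bool = False
    supporting_pairs: int = 0
    supporting_splits: int = 0
    n_exons_observed: int = 0
    n_junctions_observed: int = 0
    confidence: str = "high"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.supporting_pairs < 0 or self.supporting_splits < 0:
            raise ValueError("supporting counts must be >= 0")

    @property
    def mapped(self) -> bool:
        return self.insertion_chrom is not None

    def exon_span_string(self) -> str:
        """Human-readable exon runs, e.g. '11-14; 44' or '1-3; 4-9'."""
        parts = []
        for lo, hi, _strand in self.exon_span:
            parts.append(str(lo) if lo == hi else f"{lo}-{hi}")
        return "; ".join(parts)


def format_region(chrom: str, start: int, end: int) -> str:
    """1-based inclusive display form of a 0-based half-open interval."""
    return f"{chrom}:{start + 1}-{end}"
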