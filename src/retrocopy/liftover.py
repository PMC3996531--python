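"""Projection of transcriptome-space alignments back to genome space.

Reads aligned to a spliced transcript are converted to genome coordinates
using the transcript's exon structure: every intron crossed introduces an
N (skip) operation into the genome-space CIGAR — a "split" — and
minus-strand transcripts flip the alignment strand.  Read pairs derived
from retrocopies then show a large genome-space insert size (the mates
bracket one or more introns that are absent from the retrocopy DNA),
which is the signal the whole-genome detector filters on.
"""

from __future__ import annotations

from typing import Optional

from .models import AlignedPair, GeneModel, Mate, revcomp

#: A transcriptome-space alignment is just a :class:`Mate` whose ``chrom``
#: is a transcript identifier and whose ``pos`` is a transcript coordinate.
TranscriptAlignment = Mate


def project_to_genome(aln: Mate, model: GeneModel) -> Mate:
    """Project a transcript-space alignment into genome space.

    An M/D operation spanning an exon-exon boundary is split and an N
    operation of the intron length inserted; the strand is flipped for
    minus-strand transcripts and the stored sequence reverse-complemented
    so that it remains in reference orientation.
    """
    if not aln.is_mapped:
        return aln
    ref_len = sum(n for op, n in aln.cigar_ops if op in "MDN=X")
    if aln.pos < 0 or aln.pos + ref_len > model.transcript_length:
        raise ValueError(
            f"alignment [{aln.pos}, {aln.pos + ref_len}) extends past "
            f"transcript {model.transcript_id} of length {model.transcript_length}"
        )
    # tokens in transcript order: ('q', op, n) for query-only ops,
    # ('r', op, n, g_lo, g_hi) for reference-consuming pieces
    tokens: list[tuple] = []
    t = aln.pos
    for op, n in aln.cigar_ops:
        if op in "SI":
            tokens.append(("q", op, n))
        elif op in "MDX=":
            for t_lo, t_hi, g_lo, g_hi in model.transcript_blocks_in_range(t, t + n):
                tokens.append(("r", "M" if op == "=" else op, t_hi - t_lo, g_lo, g_hi))
            t += n
        elif op == "H":
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op!r} in transcript space")
    if model.strand == "-":
        tokens = tokens[::-1]
    # assemble genome-space CIGAR, inserting N for skipped introns
    cigar: list[tuple[str, int]] = []
    pos: Optional[int] = None
    last_end: Optional[int] = None
    for tok in tokens:
        if tok[0] == "q":
            cigar.append((tok[1], tok[2]))
            continue
        _, op, n, g_lo, g_hi = tok
        if pos is None:
            pos = g_lo
        if last_end is not None and g_lo > last_end:
            cigar.append(("N", g_lo - last_end))
        cigar.append((op, n))
        last_end = g_hi
    merged: list[tuple[str, int]] = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if model.strand == "+":
        strand, seq = aln.strand, aln.seq
    else:
        strand = "-" if aln.strand == "+" else "+"
        seq = revcomp(aln.seq)
    return Mate(
        chrom=model.chrom,
        pos=pos if pos is not None else model.start,
        strand=strand,
        cigar_ops=merged,
        mapq=aln.mapq,
        seq=seq,
    )


def project_pair(
    pair: AlignedPair, models_by_transcript: dict[str, GeneModel]
) -> AlignedPair:
    """Project both mates of a transcriptome-space pair to genome space."""
    def _one(m: Mate) -> Mate:
        if not m.is_mapped:
            return m
        model = models_by_transcript.get(m.chrom)
        if model is None:
            raise KeyError(f"unknown transcript {m.chrom}")
        return project_to_genome(m, model)

    return AlignedPair(
        read_name=pair.read_name,
        sample=pair.sample,
        mate1=_one(pair.mate1),
        mate2=_one(pair.mate2),
    )


def genome_insert_size(pair: AlignedPair) -> Optional[int]:
    """Outermost-coordinate span of a pair; None when mates are on
    different chromosomes (or either is unmapped)."""
    if not pair.same_chrom:
        return None
    return max(pair.mate1.end, pair.mate2.end) - min(pair.mate1.pos, pair.mate2.pos)
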