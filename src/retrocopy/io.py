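"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython/pyfaidx, GTF via gffutils, SAM/BAM via pysam, BED and
TSV catalogues via pandas.  All coordinates are converted to 0-based
half-open at this boundary.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedPair, GeneModel, Mate, RetrocopyEvent

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"malformed GTF record at line {lineno} of {path}")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GTF/GFF file into one :class:`GeneModel` per transcript.

    Exon indices are implied by genomic sort order plus strand; transcripts
    without exon features are rejected with a warning.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError(f"{feat.featuretype} without transcript_id in {path}")
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(feat)
            meta.setdefault(
                tid,
                {
                    "gene_id": feat.attributes.get("gene_id", [tid])[0],
                    "gene_name": feat.attributes.get(
                        "gene_name", feat.attributes.get("gene_id", [tid])
                    )[0],
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": feat.attributes.get(
                        "gene_biotype", ["protein_coding"]
                    )[0],
                },
            )
        else:
            cds.setdefault(tid, []).append((feat.start - 1, feat.end))

    models = []
    for tid, feats in exons.items():
        if not feats:
            warnings.warn(f"transcript {tid} has zero exons; skipped")
            continue
        m = meta[tid]
        intervals = sorted((f.start - 1, f.end) for f in feats)
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        models.append(
            GeneModel(
                gene_id=m["gene_id"],
                gene_name=m["gene_name"],
                transcript_id=tid,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(intervals),
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=m["biotype"],
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_name "{m.gene_name}"; gene_biotype "{m.biotype}";'
            )
            fh.write(
                "\t".join(
                    [m.chrom, "retrocopy", "gene", str(m.start + 1), str(m.end),
                     ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [m.chrom, "retrocopy", "transcript", str(m.start + 1),
                     str(m.end), ".", m.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(
                        [m.chrom, "retrocopy", "exon", str(s + 1), str(e),
                         ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )
            if m.cds_start is not None:
                for s, e in m.exons:
                    lo, hi = max(s, m.cds_start), min(e, m.cds_end)
                    if lo < hi:
                        fh.write(
                            "\t".join(
                                [m.chrom, "retrocopy", "CDS", str(lo + 1),
                                 str(hi), ".", m.strand, ".", attrs]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# SAM alignment records
# ---------------------------------------------------------------------------

_CIGAR_LETTER = "MIDNSHP=XB"


def _mate_from_record(rec: pysam.AlignedSegment) -> Mate:
    if rec.is_unmapped:
        return Mate(
            chrom=None, pos=0, strand="+", cigar_ops=[], mapq=0,
            seq=rec.query_sequence or "",
        )
    cigar = [(_CIGAR_LETTER[op], n) for op, n in rec.cigartuples]
    return Mate(
        chrom=rec.reference_name,
        pos=rec.reference_start,
        strand="-" if rec.is_reverse else "+",
        cigar_ops=cigar,
        mapq=rec.mapping_quality,
        seq=rec.query_sequence or "",
    )


def read_alignments(
    path: str | Path, sample_label: str
) -> tuple[list[AlignedPair], list[Mate]]:
    """Read a SAM/BAM file and join mates by read name.

    Returns (pairs, orphans); orphan mates — reads whose partner never
    appears — are reported on the side channel rather than dropped.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedPair] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if name in pending:
                other = pending.pop(name)
                first, second = (other, rec) if other.is_read1 else (rec, other)
                pairs.append(
                    AlignedPair(
                        read_name=name,
                        sample=sample_label,
                        mate1=_mate_from_record(first),
                        mate2=_mate_from_record(second),
                    )
                )
            else:
                pending[name] = rec
    orphans = [_mate_from_record(rec) for rec in pending.values()]
    if orphans:
        log.warning("%d orphan mates in %s", len(orphans), path)
    return pairs, orphans


def sam_header(reference_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "queryname"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in reference_lengths.items()],
        }
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    return list(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# Event catalogue (the published-table schema)
# ---------------------------------------------------------------------------

CATALOGUE_COLUMNS = [
    "sample", "cancer_type", "pseudogene", "exons", "full_length",
    "insertion_site", "target_site_dup", "internal_inversion",
]

TSD_NOT_AVAILABLE = "not_available"
TSD_NONE = "none"
TSD_LENGTH = "length"


def parse_tsd_field(value: str) -> tuple[str, Optional[int]]:
    """Type a target-site-duplication field.

    'NA' means the insertion site was unmapped or the junction unresolved
    (``not_available``); 'None' means fully mapped with no duplication; a
    value like '12 bp' is a measured duplication length.
    """
    v = str(value).strip()
    if v.upper() == "NA":
        return TSD_NOT_AVAILABLE, None
    if v.lower() == "none":
        return TSD_NONE, None
    m = re.fullmatch(r"(\d+)\s*bp", v)
    if m:
        return TSD_LENGTH, int(m.group(1))
    raise ValueError(f"unparseable target-site duplication field: {value!r}")


def _parse_yesno(value: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in ("yes", "true"):
        return True
    if v in ("no", "false"):
        return False
    raise ValueError(f"unknown {column} flag {value!r}")


@dataclass
class EventCatalogue:
    """A typed table of retrocopy events (one row per event)."""

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def read_catalogue(path: str | Path) -> EventCatalogue:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalogue {path} missing columns {missing}")
    if len(df):
        df["full_length"] = df["full_length"].map(
            lambda v: _parse_yesno(v, "full_length")
        )
        df["internal_inversion"] = df["internal_inversion"].map(
            lambda v: _parse_yesno(v, "internal_inversion")
        )
        parsed = df["target_site_dup"].map(parse_tsd_field)
        df["tsd_kind"] = [k for k, _ in parsed]
        df["tsd_bp"] = [n for _, n in parsed]
    else:
        df["tsd_kind"] = pd.Series(dtype=str)
        df["tsd_bp"] = pd.Series(dtype="Int64")
    return EventCatalogue(rows=df)


def write_catalogue(
    cat: EventCatalogue | pd.DataFrame,
    path: str | Path,
    manifest_ref: Optional[str] = None,
) -> None:
    df = cat.rows if isinstance(cat, EventCatalogue) else cat
    out = df.copy()
    for col in ("full_length", "internal_inversion"):
        if col in out.columns and out[col].dtype == bool:
            out[col] = out[col].map({True: "Yes", False: "No"})
    out = out.drop(columns=[c for c in ("tsd_kind", "tsd_bp") if c in out.columns])
    with open(path, "w") as fh:
        if manifest_ref:
            fh.write(f"# manifest: {manifest_ref}\n")
        out.to_csv(fh, sep="\t", index=False)


def events_to_frame(events: Iterable[RetrocopyEvent]) -> pd.DataFrame:
    """Detected/simulated events in the catalogue schema plus machine fields."""
    rows = []
    for ev in events:
        j = ev.junction
        if not ev.mapped:
            site = "Unmapped"
            tsd = "NA"
        elif j is None or not j.fully_mapped:
            site = f"{ev.insertion_chrom}:{(ev.insertion_point or 0) + 1}"
            tsd = "NA"
        else:
            site = f"{ev.insertion_chrom}:{(ev.insertion_point or 0) + 1}"
            tsd = f"{j.tsd_length} bp" if j.tsd_length else "None"
        rows.append(
            {
                "sample": ev.sample,
                "cancer_type": "simulated",
                "pseudogene": ev.source_gene,
                "exons": ev.exon_span_string(),
                "full_length": "Yes" if ev.full_length else "No",
                "insertion_site": site,
                "target_site_dup": tsd,
                "internal_inversion": "Yes" if ev.inverted else "No",
                "site_class": j.site_class if j else "",
                "five_prime_bp": j.five_prime_bp if j else "",
                "three_prime_bp": j.three_prime_bp if j else "",
                "polyA_bp": j.polyA_length if j else "",
                "motif_match": j.motif_match if j else "",
                "micro_5prime": "" if (j is None or j.micro_5prime is None) else j.micro_5prime,
                "micro_internal": "" if (j is None or j.micro_internal is None) else j.micro_internal,
                "supporting_pairs": ev.supporting_pairs,
                "supporting_splits": ev.supporting_splits,
                "n_exons_observed": ev.n_exons_observed,
                "n_junctions_observed": ev.n_junctions_observed,
                "confidence": ev.confidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=CATALOGUE_COLUMNS
        + ["site_class", "five_prime_bp", "three_prime_bp", "polyA_bp",
           "motif_match", "micro_5prime", "micro_internal", "supporting_pairs",
           "supporting_splits", "n_exons_observed", "n_junctions_observed",
           "confidence"],
    )
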