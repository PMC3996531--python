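"""Insertion-context annotation, catalogue summaries and the
expression-quartile enrichment test.

The catalogue summary reproduces the headline fractions a retrocopy
screen reports: how many events are 5'-truncated, inverted, carry
target-site duplications (among fully mapped sites), where the mapped
insertions land (introns, 3' UTRs, upstream, intergenic), and how many
distinct patients and cell lines are affected per cancer type.  The
enrichment test asks whether the genes serving as retrocopy templates
are unusually highly expressed in the matching tissue (top-quartile
fraction plus a two-sided Wilcoxon rank-sum test against all other
genes).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventCatalogue, TSD_LENGTH, TSD_NONE
from .models import GeneModel, InsertionJunction

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Insertion context
# ---------------------------------------------------------------------------

CTX_INTRON = "intron"
CTX_EXON = "exon"
CTX_UTR3 = "utr3"
CTX_UPSTREAM = "utr5_or_upstream"
CTX_INTERGENIC = "intergenic"
CTX_REARRANGEMENT = "at_rearrangement"


@dataclass(frozen=True)
class InsertionContext:
    klass: str
    host_gene: Optional[str] = None
    feature_index: Optional[int] = None     # intron/exon number, 1-based
    orientation_vs_host: str = "not_applicable"


def annotate_insertion(
    junction: InsertionJunction | tuple[str, int],
    models: Iterable[GeneModel],
    insert_strand: Optional[str] = None,
    upstream_window: int = 5000,
) -> list[InsertionContext]:
    """Classify an insertion point against gene features.

    A point inside two overlapping genes yields one context per gene
    (e.g. an insertion into the shared 3' UTR region of two
    opposite-strand genes).  Orientation is the insert strand relative to
    the host gene's coding strand.
    """
    if isinstance(junction, InsertionJunction):
        if junction.five_prime_bp is not None and junction.three_prime_bp is not None:
            point = min(junction.five_prime_bp, junction.three_prime_bp)
        else:
            point = junction.five_prime_bp or junction.three_prime_bp
        chrom = junction.chrom
        insert_strand = insert_strand or junction.insert_strand
    else:
        chrom, point = junction
    if point is None:
        return []

    def orient(host: GeneModel) -> str:
        if insert_strand is None:
            return "not_applicable"
        return "same" if insert_strand == host.strand else "opposite"

    contexts: list[InsertionContext] = []
    upstream_hits: list[InsertionContext] = []
    for m in models:
        if m.chrom != chrom:
            continue
        if m.start <= point < m.end:
            ei = m.exon_index_at(point)
            if ei is not None:
                klass = CTX_EXON
                if m.cds_start is not None:
                    if (m.strand == "+" and point >= m.cds_end) or (
                        m.strand == "-" and point < m.cds_start
                    ):
                        klass = CTX_UTR3
                    elif (m.strand == "+" and point < m.cds_start) or (
                        m.strand == "-" and point >= m.cds_end
                    ):
                        klass = CTX_UPSTREAM
                contexts.append(InsertionContext(
                    klass=klass, host_gene=m.gene_id, feature_index=ei,
                    orientation_vs_host=orient(m),
                ))
            else:
                contexts.append(InsertionContext(
                    klass=CTX_INTRON, host_gene=m.gene_id,
                    feature_index=m.intron_index_at(point),
                    orientation_vs_host=orient(m),
                ))
        elif (m.strand == "+" and m.start - upstream_window <= point < m.start) or (
            m.strand == "-" and m.end <= point < m.end + upstream_window
        ):
            upstream_hits.append(InsertionContext(
                klass=CTX_UPSTREAM, host_gene=m.gene_id,
                orientation_vs_host=orient(m),
            ))
    if contexts:
        return contexts
    if upstream_hits:
        return upstream_hits
    return [InsertionContext(klass=CTX_INTERGENIC)]


# ---------------------------------------------------------------------------
# Catalogue summary
# ---------------------------------------------------------------------------

_PATIENT_RE = re.compile(r"^(PD\d+)[a-z]*$")


def patient_of(sample: str, cancer_type: str = "") -> tuple[str, bool]:
    """(patient id, is_cell_line).

    Samples sharing the identifier stem before trailing lowercase letters
    (PD7354c/h/k/r) are one patient; cell lines are their own category.
    """
    if "cell line" in cancer_type.lower():
        return sample, True
    m = _PATIENT_RE.match(sample)
    return (m.group(1), False) if m else (sample, False)


def classify_site_label(label: str) -> str:
    v = label.strip()
    low = v.lower()
    if low == "unmapped" or not v:
        return "unmapped"
    if low == "intergenic":
        return CTX_INTERGENIC
    if low == "rearrangement":
        return CTX_REARRANGEMENT
    if low.startswith("intron"):
        return CTX_INTRON
    if low.startswith("exon"):
        return CTX_EXON
    if low.startswith("3' utr"):
        return CTX_UTR3
    if low.startswith("upstream") or low.startswith("5' utr"):
        return CTX_UPSTREAM
    return "mapped_other"


def _pct(n: int, d: int) -> Optional[float]:
    return None if d == 0 else 100.0 * n / d


def summarize_catalogue(cat: EventCatalogue | pd.DataFrame) -> dict:
    """Catalogue-level summary statistics.

    Percent-truncated and percent-inverted use all events as denominator;
    the TSD and polyA fractions use only events whose insertion site is
    fully mapped (TSD field is a length or 'None', not 'NA').  Insertion
    contexts are counted among events with mapped sites.
    """
    df = cat.rows if isinstance(cat, EventCatalogue) else cat
    df = df.copy()
    for col in ("full_length", "internal_inversion"):
        if len(df) and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["yes", "true"])
    n = len(df)
    out: dict = {"n_events": n}
    if n == 0:
        out.update({
            "n_primary_patients": 0, "n_cell_lines": 0,
            "pct_not_full_length": None, "pct_inverted": None,
            "n_fully_mapped": 0, "n_tsd": 0, "pct_tsd_fully_mapped": None,
            "pct_polyA_fully_mapped": None, "n_mapped_sites": 0,
            "site_context_counts": {}, "patients_by_type": {},
        })
        return out
    patients = {}
    cell_lines = set()
    by_type: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        pid, is_cl = patient_of(str(row["sample"]), str(row.get("cancer_type", "")))
        if is_cl:
            cell_lines.add(pid)
        else:
            patients[pid] = str(row.get("cancer_type", ""))
            by_type.setdefault(str(row.get("cancer_type", "")), set()).add(pid)
    out["n_primary_patients"] = len(patients)
    out["n_cell_lines"] = len(cell_lines)
    out["pct_not_full_length"] = _pct(int((~df["full_length"]).sum()), n)
    out["pct_inverted"] = _pct(int(df["internal_inversion"].sum()), n)
    fully = df[df["tsd_kind"].isin([TSD_LENGTH, TSD_NONE])]
    out["n_fully_mapped"] = len(fully)
    out["n_tsd"] = int((fully["tsd_kind"] == TSD_LENGTH).sum())
    out["pct_tsd_fully_mapped"] = _pct(out["n_tsd"], len(fully))
    if "polyA" in df.columns and len(fully):
        has_pa = fully["polyA"].astype(str).str.lower().isin(["yes", "true"])
        out["pct_polyA_fully_mapped"] = _pct(int(has_pa.sum()), len(fully))
    else:
        out["pct_polyA_fully_mapped"] = None
    site = df["insertion_site"].map(classify_site_label)
    mapped = site != "unmapped"
    out["n_mapped_sites"] = int(mapped.sum())
    out["site_context_counts"] = site[mapped].value_counts().to_dict()
    out["patients_by_type"] = {t: len(p) for t, p in sorted(by_type.items())}
    return out


def cohort_frequency(n_affected: int, cohort_size: int) -> float:
    """Percentage of a cohort carrying at least one event."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    return 100.0 * n_affected / cohort_size


# ---------------------------------------------------------------------------
# Expression enrichment
# ---------------------------------------------------------------------------

def expression_enrichment(
    template_genes: Iterable[str],
    expression: Mapping[str, float] | pd.Series,
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Are retrocopy template genes drawn from highly expressed genes?

    Returns (fraction of template genes at or above the cohort's 75th
    percentile, two-sided Wilcoxon rank-sum p-value of template genes vs
    all remaining genes).  A gene exactly at the 75th percentile counts
    as top-quartile.  The p-value uses exact enumeration of the rank-sum
    distribution when the template set is small (n <= ``exact_max_n``),
    the normal approximation otherwise.  Template genes missing from the
    expression table are logged and dropped.
    """
    expr = pd.Series(dict(expression) if not isinstance(expression, pd.Series)
                     else expression, dtype=float)
    if len(expr) < 4:
        raise ValueError("expression cohort must contain at least 4 genes")
    template = list(dict.fromkeys(template_genes))
    missing = [g for g in template if g not in expr.index]
    if missing:
        log.warning("dropping %d template genes missing from the "
                    "expression table: %s", len(missing), missing[:10])
    template = [g for g in template if g in expr.index]
    if not template:
        raise ValueError("no template genes present in the expression table")
    tvals = expr.loc[template].to_numpy()
    bvals = expr.drop(index=template).to_numpy()
    q75 = float(np.percentile(expr.to_numpy(), 75))
    fraction_top = float(np.mean(tvals >= q75))
    method = "exact" if len(tvals) <= exact_max_n else "asymptotic"
    try:
        res = stats.mannwhitneyu(tvals, bvals, alternative="two-sided",
                                 method=method)
    except ValueError:
        res = stats.mannwhitneyu(tvals, bvals, alternative="two-sided",
                                 method="asymptotic")
    return fraction_top, float(res.pvalue)
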