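"""End-to-end orchestration on simulated data.

simulate -> detect (genome and exome modes) -> map insertions -> annotate
-> summarize, with a recovery report comparing calls against the
simulator's truth records (per-feature precision/recall), plus a run
manifest (tool version, config hash, input checksums, seed, per-stage
record counts) referenced from every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import __version__
from . import io as rio
from .annotate import annotate_insertion, summarize_catalogue
from .breakpoints import map_insertion_site
from .exome_mode import detect_exome
from .genome_mode import DetectionReport, FilterThresholds, call_candidates
from .liftover import project_pair
from .models import AlignedPair, GeneModel, RetrocopyEvent
from .simulate import SimConfig, SimResult, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def reference(self) -> str:
        return f"retrocopy-{self.version}-{self.config_hash[:12]}"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _hash_config(config: SimConfig, thresholds: FilterThresholds) -> str:
    text = repr(dataclasses.astuple(config)) + repr(dataclasses.astuple(thresholds))
    return hashlib.sha256(text.encode()).hexdigest()


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_projected_pairs(
    sam_path: str | Path, sample: str, models: Iterable[GeneModel]
) -> list[AlignedPair]:
    """Read a transcriptome-space SAM and project every pair to genome space."""
    by_tid = {m.transcript_id: m for m in models}
    pairs, _orphans = rio.read_alignments(sam_path, sample)
    return [project_pair(p, by_tid) for p in pairs]


def capture_filter(
    pairs: Iterable[AlignedPair], models: Iterable[GeneModel], pad: int = 100
) -> list[AlignedPair]:
    """Restrict pairs to an exome capture design (annotated exons +/- pad)."""
    targets: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        for s, e in m.exons:
            targets.setdefault(m.chrom, []).append((s - pad, e + pad))
    for c in targets:
        targets[c].sort()

    def on_target(pair: AlignedPair) -> bool:
        for m in pair.mates:
            if not m.is_mapped:
                return False
            ivs = targets.get(m.chrom, [])
            if not any(m.pos < e and s < m.end for s, e in ivs):
                return False
        return True

    return [p for p in pairs if on_target(p)]


@dataclass
class RecoveryReport:
    n_truth: int
    n_called: int
    n_called_true: int
    n_false_positive: int
    recall: float
    n_breakpoints_comparable: int
    n_breakpoints_exact: int
    n_tsd_comparable: int
    n_tsd_exact: int
    n_polyA_true: int
    n_polyA_detected: int
    n_inversions_true: int
    n_inversions_detected: int
    inversion_no_duplication_violations: int
    exome_recall: float
    exome_subset_of_genome: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_to_truth(
    sim: SimResult,
    events: list[RetrocopyEvent],
    exome_events: list[RetrocopyEvent],
) -> RecoveryReport:
    truth_by_gene = {t.event.source_gene: t for t in sim.truths}
    called = {ev.source_gene: ev for ev in events}
    true_calls = set(called) & set(truth_by_gene)
    bp_comp = bp_exact = tsd_comp = tsd_exact = 0
    pa_true = pa_det = inv_true = inv_det = inv_dup = 0
    for gene in sorted(true_calls):
        t, ev = truth_by_gene[gene], called[gene]
        j = ev.junction
        if t.polyA_len > 0:
            pa_true += 1
            if j is not None and j.polyA_length >= 10:
                pa_det += 1
        if t.inversion_k is not None:
            inv_true += 1
            if ev.inverted:
                inv_det += 1
            if "inversion_duplication" in ev.notes:
                inv_dup += 1
        if j is None or not j.fully_mapped:
            continue
        bp_comp += 1
        want = {t.left_ref_end, t.right_ref_start}
        got = {j.five_prime_bp, j.three_prime_bp}
        if ev.insertion_chrom == t.chrom and got == want:
            bp_exact += 1
        tsd_comp += 1
        if j.site_class == t.site_class and j.tsd_length == t.tsd_len \
                and j.deletion_length == t.deletion_len:
            tsd_exact += 1
    exome_called = {ev.source_gene for ev in exome_events}
    n_truth = len(sim.truths)
    return RecoveryReport(
        n_truth=n_truth,
        n_called=len(events),
        n_called_true=len(true_calls),
        n_false_positive=len(set(called) - set(truth_by_gene)),
        recall=len(true_calls) / n_truth if n_truth else 1.0,
        n_breakpoints_comparable=bp_comp,
        n_breakpoints_exact=bp_exact,
        n_tsd_comparable=tsd_comp,
        n_tsd_exact=tsd_exact,
        n_polyA_true=pa_true,
        n_polyA_detected=pa_det,
        n_inversions_true=inv_true,
        n_inversions_detected=inv_det,
        inversion_no_duplication_violations=inv_dup,
        exome_recall=(len(exome_called & set(truth_by_gene)) / n_truth
                      if n_truth else 1.0),
        exome_subset_of_genome=exome_called <= set(called) | set(truth_by_gene),
    )


@dataclass
class PipelineResult:
    sim: SimResult
    genome_report: DetectionReport
    events: list[RetrocopyEvent]
    exome_events: list[RetrocopyEvent]
    exome_rejected: list
    recovery: RecoveryReport
    summary: dict
    manifest: RunManifest
    out_dir: Path


def run_end_to_end(
    config: SimConfig,
    out_dir: str | Path,
    thresholds: FilterThresholds = FilterThresholds(),
    germline_deletions: Optional[list[tuple[str, int, int]]] = None,
) -> PipelineResult:
    """Simulate a dataset and run both detection modes plus mapping.

    Stages: simulate -> project transcriptome alignments -> genome-mode
    candidate calling -> insertion-site mapping -> exome-mode calling on
    capture-restricted reads -> annotation -> catalogue summary ->
    truth comparison.  Any stage failure aborts with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim = simulate_dataset(config, out_dir / "sim")
        models = sim.models

        stage = "load+project"
        tum_proj = load_projected_pairs(sim.sam("tumour", "transcriptome"),
                                        "tumour", models)
        norm_proj = load_projected_pairs(sim.sam("normal", "transcriptome"),
                                         "normal", models)
        panel_proj: list[AlignedPair] = []
        for name in sim.panel_names:
            panel_proj += load_projected_pairs(sim.sam(name, "transcriptome"),
                                               name, models)

        stage = "detect-genome"
        report = call_candidates(tum_proj, norm_proj, panel_proj, models,
                                 thresholds)
        events = [ev for ev in report.events if ev.confidence == "high"]

        stage = "map-insertions"
        tum_genome_pairs, _ = rio.read_alignments(sim.sam("tumour"), "tumour")
        by_gene_model = {m.gene_id: m for m in models}
        for ev in events:
            map_insertion_site(ev, by_gene_model[ev.source_gene],
                               tum_genome_pairs, sim.reference)

        stage = "detect-exome"
        norm_genome, _ = rio.read_alignments(sim.sam("normal"), "normal")
        panel_genome: list[AlignedPair] = []
        for name in sim.panel_names:
            ppairs, _ = rio.read_alignments(sim.sam(name), name)
            panel_genome += ppairs
        exome_events, exome_rejected = detect_exome(
            capture_filter(tum_genome_pairs, models),
            capture_filter(norm_genome, models),
            capture_filter(panel_genome, models),
            models, thresholds, germline_deletions,
        )

        stage = "annotate"
        for ev in events:
            if ev.junction is not None and ev.mapped:
                ctxs = annotate_insertion(ev.junction, models)
                ev.notes = (ev.notes + ";" if ev.notes else "") + ",".join(
                    f"{c.klass}"
                    + (f"_{c.feature_index}" if c.feature_index else "")
                    + (f":{c.host_gene}:{c.orientation_vs_host}"
                       if c.host_gene else "")
                    for c in ctxs
                )

        stage = "summarize"
        frame = rio.events_to_frame(events)
        summary = summarize_catalogue(
            frame.assign(tsd_kind=[
                rio.parse_tsd_field(v)[0] for v in frame["target_site_dup"]
            ], tsd_bp=[
                rio.parse_tsd_field(v)[1] for v in frame["target_site_dup"]
            ])
        )
        recovery = compare_to_truth(sim, events, exome_events)

        stage = "write-outputs"
        manifest = RunManifest(
            version=__version__,
            seed=config.seed,
            config_hash=_hash_config(config, thresholds),
            input_checksums={
                p.name: _checksum(p)
                for p in sorted((out_dir / "sim").glob("*"))
                if p.suffix in (".fa", ".gtf", ".sam", ".tsv")
            },
            stage_counts={
                "truth_events": len(sim.truths),
                "tumour_projected_pairs": len(tum_proj),
                "genome_candidates": len(events),
                "exome_candidates": len(exome_events),
                **{k: v for k, v in report.attrition.items()},
            },
        )
        (out_dir / "manifest.json").write_text(manifest.to_json())
        rio.write_catalogue(frame, out_dir / "events.tsv",
                            manifest_ref=manifest.reference)
        rio.write_catalogue(rio.events_to_frame(exome_events),
                            out_dir / "events.exome.tsv",
                            manifest_ref=manifest.reference)
        (out_dir / "recovery.json").write_text(
            json.dumps(recovery.to_dict(), indent=2, sort_keys=True))
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str))
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    return PipelineResult(
        sim=sim, genome_report=report, events=events,
        exome_events=exome_events, exome_rejected=exome_rejected,
        recovery=recovery, summary=summary, manifest=manifest,
        out_dir=out_dir,
    )
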