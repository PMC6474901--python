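"""End-to-end orchestration: transcripts -> six-frame ORFs -> PSM
mapping -> selection filters -> characterization -> candidate report.

Every protein that enters the pipeline leaves it exactly once, either
in the accepted report or in the rejection log with a machine-readable
reason; reruns on identical inputs produce identical report bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import properties, selection, transcriptome
from .evidence import DigestParams, ProteinEvidence, group_proteins, map_psms, read_psm_table
from .repeats import find_tandem_repeats
from .scales import PKA_SETS, EMBOSS
from .selection import SelectionThresholds
from .simulate import SAMPLES

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    transcripts_fasta: str
    psm_tables: list[str]
    hits_table: str | None = None
    classes_table: str | None = None
    signals_table: str | None = None
    overrides: list[str] = field(default_factory=list)
    out_dir: str = "byssomap_out"
    min_aa: int = 30
    orf_mode: str = "keep_all"
    missed_cleavages: int = 1
    il_equivalent: bool = True
    pka: str = "emboss"
    hydropathy_window: int = 9
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = SelectionThresholds(**thr)
        return cfg


@dataclass
class CandidateReport:
    accepted: pd.DataFrame
    rejected: pd.DataFrame
    summary: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _read_signal_annotations(path: str | Path | None) -> dict[str, int]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pka = PKA_SETS.get(config.pka, EMBOSS)

    # stage: transcriptome
    try:
        transcripts = transcriptome.read_transcripts(config.transcripts_fasta)
    except Exception as exc:
        raise StageError("read_transcripts", str(exc)) from exc
    isoforms = []
    for t in transcripts:
        frames = transcriptome.six_frame_translate(t)
        isoforms.extend(
            transcriptome.extract_orfs(
                frames, min_aa=config.min_aa, mode=config.orf_mode,
                transcript_id=t.id, family=t.component_id,
            )
        )
    log.info("translated %d transcripts into %d ORFs", len(transcripts), len(isoforms))

    # stage: signal annotation (file > existing > heuristic), then
    # variant completion within components for the still-unannotated
    annotations = _read_signal_annotations(config.signals_table)
    for iso in isoforms:
        passed, ann = selection.signal_peptide_gate(iso, annotations)
        if passed:
            iso.signal = ann
    by_component: dict[str, list] = {}
    for iso in isoforms:
        by_component.setdefault(iso.family, []).append(iso)
    isoforms = []
    for comp, members in sorted(by_component.items()):
        isoforms.extend(transcriptome.complete_signal_from_variants(members))

    # stage: PSM mapping
    psms = []
    for table in config.psm_tables:
        psms.extend(read_psm_table(table))
    params = DigestParams(missed_cleavages=config.missed_cleavages)
    evidence, unmatched = map_psms(psms, isoforms, params, config.il_equivalent)
    if unmatched:
        pd.DataFrame([{"sample": p.sample, "peptide": p.peptide} for p in unmatched]
                     ).to_csv(out_dir / "unmatched_psms.tsv", sep="\t", index=False)

    # stage: selection
    accepted, rejections = selection.apply_score_filters(
        evidence, config.thresholds, overrides=config.overrides
    )
    if config.hits_table:
        hits = selection.read_homology_table(config.hits_table, config.classes_table)
        accepted, contaminant_rej = selection.contaminant_filter(
            accepted, hits, config.thresholds
        )
        rejections.extend(contaminant_rej)
    secreted: list[ProteinEvidence] = []
    for ev in accepted:
        if ev.isoform.signal is not None:
            secreted.append(ev)
        else:
            rejections.append(
                selection.Rejection(ev.isoform.isoform_id, "no_signal_peptide")
            )
    groups = group_proteins(secreted)

    # stage: characterization and report
    rows = []
    by_family: dict[str, list[ProteinEvidence]] = {}
    for ev in secreted:
        by_family.setdefault(ev.isoform.family, []).append(ev)
    for family, members in sorted(by_family.items()):
        profiles = {}
        masses = []
        for ev in members:
            prof = properties.profile(
                ev.isoform, pka=pka, window=config.hydropathy_window
            )
            profiles[ev.isoform.isoform_id] = prof
            masses.append(prof.avg_mass_kda * 1000.0)
        labelled = transcriptome.assign_variant_names(
            [ev.isoform for ev in members], masses
        )
        for ev, iso in zip(members, labelled):
            ev.isoform = iso
        rep = selection.select_representative(list(zip(members, masses)))
        for ev in members:
            prof = profiles[ev.isoform.isoform_id]
            mature, _ = properties.mature_sequence(ev.isoform)
            repeats = find_tandem_repeats(mature)
            top4 = sorted(prof.molpct.items(), key=lambda kv: (-kv[1], kv[0]))[:4]
            rows.append({
                "family": family,
                "variant": ev.isoform.variant_label,
                "isoform_id": ev.isoform.isoform_id,
                "representative": ev is rep,
                "mature_len": prof.mature_len,
                "MW_kDa": round(prof.avg_mass_kda, 1),
                "pI": round(prof.pI, 1),
                "charge_pH7": round(prof.charge_at_pH7, 1),
                "category": prof.category,
                "top4_molpct": ";".join(f"{aa}:{v:.1f}" for aa, v in top4),
                **{f"spectra_{s}": ev.spectral_counts.get(s, 0) for s in SAMPLES},
                "coverage_pct": round(ev.coverage_pct, 1),
                "n_repeats": len(repeats),
                "repeats": ";".join(
                    f"{h.unit}x{h.copies}@{h.start}" for h in repeats[:5]
                ),
                "nterm_segment_pI": (
                    round(prof.nterm_segment_pI, 1)
                    if prof.nterm_segment_pI is not None else ""
                ),
                "cterm_segment_pI": (
                    round(prof.cterm_segment_pI, 1)
                    if prof.cterm_segment_pI is not None else ""
                ),
            })
    accepted_df = pd.DataFrame(rows)
    rejected_df = pd.DataFrame(
        [{"isoform_id": r.item_id, "reason": r.reason, "detail": r.detail}
         for r in rejections]
    )
    summary = {
        "n_transcripts": len(transcripts),
        "n_isoforms": len(isoforms),
        "n_psms": len(psms),
        "n_matched_psms": len(psms) - len(unmatched),
        "n_evidence": len(evidence),
        "n_accepted": len(secreted),
        "n_rejected": len(rejections),
        "n_protein_groups": len(groups),
        "spectra_per_sample": {
            s: int(sum(ev.spectral_counts.get(s, 0) for ev in secreted))
            for s in SAMPLES
        },
    }
    accepted_df.to_csv(out_dir / "accepted.tsv", sep="\t", index=False)
    rejected_df.to_csv(out_dir / "rejected.tsv", sep="\t", index=False)
    log.info("pipeline summary: %s", summary)
    return CandidateReport(accepted=accepted_df, rejected=rejected_df, summary=summary)
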