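"""Candidate selection: score thresholds, contaminant homology filter,
signal-peptide gate and family-representative choice.

The filters encode the acceptance rules used for novel secreted byssal
proteins: a protein needs a -10lgP protein score >= 50, at least two
qualifying peptide spectra (each peptide -10lgP >= 15; purely de novo
peptides additionally need ALC >= 80% and by default do not count
toward the spectrum minimum), no strong homology (E < 1e-6) to a known
cellular contaminant, and a signal peptide from any source.  Named
overrides can bypass the score gate with a logged justification, the
automatable analogue of manual spectrum confirmation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import ProteinEvidence
from .scales import KYTE_DOOLITTLE
from .transcriptome import ProteinIsoform, SignalAnnotation

log = logging.getLogger(__name__)

SMALL_RESIDUES = frozenset("AGSCTV")  # allowed at -3/-1 of a cleavage site


@dataclass(frozen=True)
class SelectionThresholds:
    min_peptide_score: float = 15.0
    min_protein_score: float = 50.0
    min_alc_pct: float = 80.0
    min_spectra: int = 2
    contaminant_evalue_max: float = 1e-6
    count_de_novo_spectra: bool = False

    def __post_init__(self) -> None:
        if min(self.min_peptide_score, self.min_protein_score,
               self.min_alc_pct, self.min_spectra,
               self.contaminant_evalue_max) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_alc_pct > 100:
            raise ValueError("min_alc_pct must be <= 100")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    evalue: float
    subject_class: str = "other"  # contaminant_db | byssal_allowlist | other

    def __post_init__(self) -> None:
        if not self.evalue >= 0:
            raise ValueError("evalue must be finite and >= 0")


@dataclass(frozen=True)
class Rejection:
    item_id: str
    reason: str
    detail: str = ""


def counted_psms(ev: ProteinEvidence, thresholds: SelectionThresholds) -> list:
    """PSMs of an evidence record that qualify under the thresholds
    (peptide score >= minimum; de novo additionally ALC >= minimum)."""
    counted = []
    for psm in ev.psms:
        if psm.peptide_score is None or psm.peptide_score < thresholds.min_peptide_score:
            continue
        if psm.is_de_novo_only and (psm.alc is None or psm.alc < thresholds.min_alc_pct):
            continue
        counted.append(psm)
    return counted


def apply_score_filters(
    evidence: Sequence[ProteinEvidence],
    thresholds: SelectionThresholds = SelectionThresholds(),
    overrides: Iterable[str] = (),
) -> tuple[list[ProteinEvidence], list[Rejection]]:
    """Apply the score acceptance rules to per-isoform evidence.

    Returns the accepted evidence and a rejection log; override ids are
    accepted regardless of scores, with the bypass logged.
    """
    overrides = set(overrides)
    accepted: list[ProteinEvidence] = []
    rejections: list[Rejection] = []
    for ev in evidence:
        iid = ev.isoform.isoform_id
        if iid in overrides:
            log.info("override: accepting %s despite score gates", iid)
            accepted.append(ev)
            continue
        if ev.protein_score is None:
            rejections.append(Rejection(iid, "unscored"))
            continue
        counted = counted_psms(ev, thresholds)
        n_spectra = sum(
            1 for p in counted
            if thresholds.count_de_novo_spectra or not p.is_de_novo_only
        )
        if ev.protein_score < thresholds.min_protein_score:
            rejections.append(
                Rejection(iid, "protein_score",
                          f"{ev.protein_score:.1f} < {thresholds.min_protein_score}")
            )
        elif n_spectra < thresholds.min_spectra:
            rejections.append(
                Rejection(iid, "min_spectra", f"{n_spectra} < {thresholds.min_spectra}")
            )
        else:
            accepted.append(ev)
    return accepted, rejections


def contaminant_filter(
    evidence: Sequence[ProteinEvidence],
    hits: Sequence[HomologyHit],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> tuple[list[ProteinEvidence], list[Rejection]]:
    """Reject isoforms with a contaminant-database hit at E < cutoff.

    Hits to the byssal allowlist never reject (homology to known byssal
    proteins is expected); isoforms without hits are retained.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    retained: list[ProteinEvidence] = []
    rejections: list[Rejection] = []
    for ev in evidence:
        iid = ev.isoform.isoform_id
        contaminant = [
            h for h in by_query.get(iid, [])
            if h.subject_class == "contaminant_db"
            and h.evalue < thresholds.contaminant_evalue_max
        ]
        if contaminant:
            best = min(contaminant, key=lambda h: h.evalue)
            rejections.append(
                Rejection(iid, "contaminant",
                          f"{best.subject_id} at E={best.evalue:.2g}")
            )
        else:
            retained.append(ev)
    return retained, rejections


def predict_signal_heuristic(aa_sequence: str) -> SignalAnnotation | None:
    """Classical n/h/c signal-peptide heuristic with the (-3,-1) rule.

    A cleavage site in positions 15-35 is returned iff (a) positions
    1-5 carry non-negative net charge, (b) a hydrophobic core of >= 6
    residues with mean Kyte-Doolittle >= 1.6 lies within positions
    3-20, and (c) the residues at -3 and -1 of the site are small
    (A/G/S/C/T/V).  Candidate sites are scored by core hydrophobicity
    plus a small-residue bonus, minus a penalty for distance from the
    typical c-region position (about six residues past the core end);
    ties take the smallest position.  This is a lightweight stand-in
    for a trained signal-peptide predictor and is always overridden by
    annotations.
    """
    seq = aa_sequence
    if len(seq) < 17:
        return None
    # (a) weakly basic n-region
    charge5 = sum(seq[:5].count(r) for r in "KR") - sum(seq[:5].count(r) for r in "DE")
    if charge5 < 0:
        return None
    # (b) most hydrophobic core (>= 6 residues) within positions 3..20
    best_core = None
    for length in range(6, 19):
        for i in range(2, 20 - length + 1):
            frag = seq[i:i + length]
            if len(frag) < length:
                break
            mean_kd = sum(KYTE_DOOLITTLE.get(c, 0.0) for c in frag) / length
            if mean_kd >= 1.6 and (best_core is None or mean_kd > best_core[0]):
                best_core = (mean_kd, i + length)  # (hydrophobicity, core end)
    if best_core is None:
        return None
    core_kd, core_end = best_core
    # (c) candidate cleavage sites with small residues at -3 and -1
    best = None
    for pos in range(15, min(35, len(seq) - 1) + 1):
        m1, m3 = seq[pos - 1], seq[pos - 3]
        if m1 not in SMALL_RESIDUES or m3 not in SMALL_RESIDUES:
            continue
        bonus = 0.2 * ((m1 in "AGS") + (m3 in "AGS"))
        score = core_kd + bonus - 0.3 * abs(pos - (core_end + 6))
        if best is None or score > best[0]:
            best = (score, pos)
    if best is None:
        return None
    return SignalAnnotation(cleavage_pos=best[1], source="heuristic")


def signal_peptide_gate(
    isoform: ProteinIsoform,
    annotations: Mapping[str, int] | None = None,
    use_heuristic: bool = True,
) -> tuple[bool, SignalAnnotation | None]:
    """Secreted-protein gate: pass iff a signal annotation exists.

    Sources in precedence order: annotation file, an annotation already
    carried by the isoform (e.g. variant completion), then the
    heuristic.  Conflicting cleavage sites keep the annotation file's
    and log the conflict.
    """
    annotations = annotations or {}
    file_pos = annotations.get(isoform.isoform_id, annotations.get(isoform.transcript_id))
    existing = isoform.signal
    if file_pos is not None:
        ann = SignalAnnotation(cleavage_pos=int(file_pos), source="annotation_file")
        if existing is not None and existing.cleavage_pos != ann.cleavage_pos:
            log.warning(
                "conflicting cleavage sites for %s (%d file vs %d %s); keeping file",
                isoform.isoform_id, ann.cleavage_pos, existing.cleavage_pos,
                existing.source,
            )
        return True, ann
    if existing is not None:
        return True, existing
    if use_heuristic:
        pred = predict_signal_heuristic(isoform.aa_sequence)
        if pred is not None:
            return True, pred
    return False, None


def select_representative(
    family: Sequence[tuple[ProteinEvidence, float]],
    priority: tuple[str, ...] = ("spectra", "mass"),
) -> ProteinEvidence:
    """Pick the family representative.

    ``family`` pairs evidence with the mature mass (Da).  Default
    priority: highest total spectral count, then largest mature mass,
    then sequence (deterministic tiebreak).
    """
    if not family:
        raise ValueError("empty family")

    def sort_key(item: tuple[ProteinEvidence, float]):
        ev, mass = item
        keys = []
        for crit in priority:
            if crit == "spectra":
                keys.append(-ev.total_spectra)
            elif crit == "mass":
                keys.append(-mass)
            else:
                raise ValueError(f"unknown priority criterion {crit!r}")
        keys.append(ev.isoform.aa_sequence)
        return tuple(keys)

    return min(family, key=sort_key)[0]


BLAST_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_homology_table(
    hits_path: str | Path, classes_path: str | Path | None = None
) -> list[HomologyHit]:
    """Read a 12-column tabular local-alignment table (BLAST outfmt 6)
    plus an optional subject-class sidecar TSV (subject, class)."""
    df = pd.read_csv(hits_path, sep="\t", header=None, names=BLAST_COLUMNS)
    classes: dict[str, str] = {}
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, sep="\t")
        classes = dict(zip(cdf.iloc[:, 0].astype(str), cdf.iloc[:, 1].astype(str)))
    return [
        HomologyHit(
            query_id=str(r.query),
            subject_id=str(r.subject),
            evalue=float(r.evalue),
            subject_class=classes.get(str(r.subject), "other"),
        )
        for r in df.itertuples(index=False)
    ]
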