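"""Peptide evidence: tryptic digestion, modification-aware matching of
peptide-spectrum matches (PSMs) to translated isoforms, spectral
counting, coverage and parsimony grouping.

Matching is sequence-level: PSM tables arrive already scored by the
upstream search engine, so mass tolerances travel as metadata only.
Modification marks follow the lower-case convention used in byssal
protein tables: ``n``/``q`` for deamidated Asn/Gln and ``y`` for
hydroxylated Tyr (DOPA); marks never change which template residue a
peptide matches, they only annotate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd
from pyteomics import parser as _pyt_parser

from .transcriptome import ProteinIsoform

log = logging.getLogger(__name__)

# cleave C-terminal to K/R unless followed by P (also cuts at a
# C-terminal K/R, which the expasy lookahead variant would miss)
TRYPSIN_RULE = r"[KR](?!P)"

_MOD_NAMES = {"n": "deamidation", "q": "deamidation", "y": "hydroxylation"}


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    missed_cleavages: int = 1
    min_len: int = 5
    max_len: int = 60

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only tryptic digestion is supported")
        if not 0 <= self.missed_cleavages <= 2:
            raise ValueError("missed_cleavages must be 0..2")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid peptide length bounds")


@dataclass(frozen=True)
class ToleranceConfig:
    """Instrument tolerances (metadata only; matching is sequence-level)."""

    parent_ppm: float = 5.0
    fragment_da: float = 0.01

    def __post_init__(self) -> None:
        if self.parent_ppm <= 0 or self.fragment_da <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PsmRecord:
    peptide: str  # may carry lower-case modification marks
    peptide_score: float | None
    sample: str
    alc: float | None = None
    is_de_novo_only: bool = False
    protein_score: float | None = None
    transcript_hint: str | None = None

    def __post_init__(self) -> None:
        if len(self.peptide) < 5:
            raise ValueError(f"peptide {self.peptide!r} shorter than 5 residues")
        if self.peptide_score is not None and self.peptide_score < 0:
            raise ValueError("negative peptide score")
        if self.alc is not None and not 0 <= self.alc <= 100:
            raise ValueError("ALC outside [0, 100]")


class ModifiedPeptide(NamedTuple):
    backbone: str  # plain upper-case match key
    mods: tuple[tuple[int, str], ...]  # (1-based position, modification)


@dataclass
class ProteinEvidence:
    isoform: ProteinIsoform
    protein_score: float
    matched_peptides: dict[str, list[int]]  # backbone -> 1-based start positions
    spectral_counts: dict[str, int]  # sample -> count
    coverage_pct: float
    n_unique_peptides: int
    psms: list[PsmRecord] = field(default_factory=list)
    nontryptic_warnings: list[str] = field(default_factory=list)

    @property
    def total_spectra(self) -> int:
        return sum(self.spectral_counts.values())


def digest(aa_sequence: str, params: DigestParams | None = None) -> list[tuple[str, int]]:
    """In-silico tryptic peptides with 1-based start positions.

    Cleaves C-terminal to K/R except before P; retains peptides with up
    to ``missed_cleavages`` internal sites within the length bounds.
    """
    if not aa_sequence:
        raise ValueError("empty sequence")
    params = params or DigestParams()
    seen: set[tuple[str, int]] = set()
    out = []
    for start, pep in _pyt_parser.icleave(
        aa_sequence, TRYPSIN_RULE, missed_cleavages=params.missed_cleavages,
        min_length=params.min_len,
    ):
        item = (pep, start + 1)
        if len(pep) <= params.max_len and item not in seen:
            seen.add(item)
            out.append(item)
    return out


def expand_modification_keys(peptide: str) -> ModifiedPeptide:
    """Strip modification marks to a plain match key.

    Lower-case ``n``/``q``/``y`` mark deamidated N/Q or hydroxylated Y;
    any other lower-case residue is a validation error.  The backbone
    is the mark-stripped upper-case sequence against which templates
    are matched.
    """
    mods = []
    backbone = []
    for i, c in enumerate(peptide):
        if c.islower():
            if c not in _MOD_NAMES:
                raise ValueError(
                    f"modification mark {c!r} at position {i + 1}: "
                    "only n/q (deamidation) and y (hydroxylation) are allowed"
                )
            mods.append((i + 1, _MOD_NAMES[c]))
        backbone.append(c.upper())
    return ModifiedPeptide("".join(backbone), tuple(mods))


def _fold_il(seq: str) -> str:
    return seq.replace("I", "L")


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 1-based match starts (overlapping)."""
    starts = []
    i = haystack.find(needle)
    while i >= 0:
        starts.append(i + 1)
        i = haystack.find(needle, i + 1)
    return starts


def _is_tryptic(seq: str, start0: int, length: int) -> bool:
    nt_ok = start0 == 0 or (seq[start0 - 1] in "KR" and seq[start0] != "P")
    end = start0 + length
    ct_ok = end == len(seq) or (seq[end - 1] in "KR" and seq[end] != "P")
    return nt_ok and ct_ok


def map_psms(
    psms: Sequence[PsmRecord],
    isoforms: Sequence[ProteinIsoform],
    params: DigestParams | None = None,
    il_equivalent: bool = True,
) -> tuple[list[ProteinEvidence], list[PsmRecord]]:
    """Match PSM backbones to isoform sequences by exact substring.

    I and L are treated as equal by default (indistinguishable by MS).
    A PSM may hit several isoforms; shared-peptide ambiguity is kept.
    Returns per-isoform evidence plus the unmatched PSMs.  Coverage is
    computed over the mature sequence; peptides with non-tryptic
    termini match but are flagged with a warning.
    """
    evidence: list[ProteinEvidence] = []
    matched_any: set[int] = set()
    folded = [(_fold_il(iso.aa_sequence) if il_equivalent else iso.aa_sequence)
              for iso in isoforms]
    for iso, target in zip(isoforms, folded):
        matched: dict[str, list[int]] = {}
        counts: dict[str, int] = {}
        warnings: list[str] = []
        prot_scores: list[float] = []
        pep_best: dict[str, float] = {}
        matched_psms: list[PsmRecord] = []
        for j, psm in enumerate(psms):
            backbone = expand_modification_keys(psm.peptide).backbone
            key = _fold_il(backbone) if il_equivalent else backbone
            starts = _find_all(target, key)
            if not starts:
                continue
            matched_any.add(j)
            matched_psms.append(psm)
            matched.setdefault(backbone, []).extend(
                s for s in starts if s not in matched.get(backbone, [])
            )
            counts[psm.sample] = counts.get(psm.sample, 0) + 1
            if psm.protein_score is not None:
                prot_scores.append(psm.protein_score)
            if psm.peptide_score is not None:
                pep_best[backbone] = max(pep_best.get(backbone, 0.0), psm.peptide_score)
            for s in starts:
                if not _is_tryptic(iso.aa_sequence, s - 1, len(backbone)):
                    warnings.append(f"non-tryptic terminus for {backbone} at {s}")
        if not matched:
            continue
        mature_start = iso.mature_start
        mature_len = len(iso.aa_sequence) - mature_start
        covered: set[int] = set()
        for backbone, starts in matched.items():
            for s in starts:
                for p in range(s - 1, s - 1 + len(backbone)):
                    if p >= mature_start:
                        covered.add(p)
        coverage = 100.0 * len(covered) / mature_len if mature_len else 0.0
        # protein score: best upstream protein-level score; recomputed
        # as the sum of per-peptide best scores when absent (fallback)
        score = max(prot_scores) if prot_scores else sum(pep_best.values())
        evidence.append(
            ProteinEvidence(
                isoform=iso,
                protein_score=score,
                matched_peptides=matched,
                spectral_counts=counts,
                coverage_pct=coverage,
                n_unique_peptides=len(matched),
                psms=matched_psms,
                nontryptic_warnings=sorted(set(warnings)),
            )
        )
    unmatched = [p for j, p in enumerate(psms) if j not in matched_any]
    if unmatched:
        log.info("%d PSMs matched no isoform", len(unmatched))
    return evidence, unmatched


@dataclass
class ProteinGroup:
    anchor: ProteinEvidence
    members: list[ProteinEvidence]


def group_proteins(evidence: Sequence[ProteinEvidence]) -> list[ProteinGroup]:
    """Parsimony grouping: merge isoforms whose peptide sets are equal
    to or subsets of another's, anchored on the largest peptide set
    (ties broken by higher protein score)."""
    order = sorted(
        evidence,
        key=lambda e: (-len(e.matched_peptides), -e.protein_score,
                       e.isoform.isoform_id),
    )
    groups: list[ProteinGroup] = []
    for ev in order:
        peps = set(ev.matched_peptides)
        home = None
        for g in groups:
            if peps <= set(g.anchor.matched_peptides):
                home = g
                break
        if home is None:
            groups.append(ProteinGroup(anchor=ev, members=[ev]))
        else:
            home.members.append(ev)
    return groups


PSM_COLUMNS = ["sample", "peptide", "peptide_score", "alc",
               "is_de_novo_only", "protein_score", "transcript_hint"]


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Read a PSM TSV (columns: sample, peptide, peptide_score, alc,
    is_de_novo_only, protein_score, transcript_hint; the last three
    optional)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "peptide": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PsmRecord(
                peptide=row.peptide,
                peptide_score=_opt_float(getattr(row, "peptide_score", None)),
                sample=row.sample,
                alc=_opt_float(getattr(row, "alc", None)),
                is_de_novo_only=bool(getattr(row, "is_de_novo_only", False)),
                protein_score=_opt_float(getattr(row, "protein_score", None)),
                transcript_hint=_opt_str(getattr(row, "transcript_hint", None)),
            )
        )
    return records


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return str(v)
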