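"""Seeded synthetic datasets with planted ground truth.

Generates a toy foot-transcriptome experiment end to end: secreted
byssal-like proteins (signal peptide, byssal residue bias, optional
planted tandem repeat, spliced variants), cellular contaminants
(no signal, strong homology hits), reverse-translated transcripts with
UTRs and optional 5' truncation, per-sample PSM tables whose score
distributions straddle the acceptance thresholds, homology and
signal-annotation sidecars, and a JSON truth file.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .evidence import DigestParams, digest

SAMPLES = ("whole_TP", "band6", "band7", "band14")

#: Gel-band visibility windows (kDa), emulating SDS-PAGE band clipping.
BAND_WINDOWS = {
    "band6": (4.5, 7.5),
    "band7": (5.5, 8.5),
    "band14": (11.0, 17.0),
}

# byssal-like residue bias for mature regions (G/Y/P/N/S-heavy)
_MATURE_POOL = "GGGGYYYPPPNNSSKKDDRRTTQAEVWC"
_CONTAM_POOL = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "LAVIF"

_AVG_RESIDUE_DA = 110.0

# aa -> codons (standard code), sorted for determinism
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
_STOP_CODONS = sorted(CodonTable.unambiguous_dna_by_id[1].stop_codons)


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 6
    variants_per_family: int = 2
    n_contaminants: int = 3
    mass_range_kda: tuple[float, float] = (4.0, 22.0)
    repeat_library: tuple[tuple[str, int], ...] = (
        ("PKYPGGGN", 4), ("YPTYPEKK", 5), ("GNVVGEQ", 4),
    )
    repeat_probability: float = 0.5
    psms_per_sample: int = 3
    n_noise_psms: int = 30
    true_score_mu: float = 35.0
    true_score_sd: float = 8.0
    noise_score_mu: float = 10.0
    noise_score_sd: float = 5.0
    protein_score_mu: float = 80.0
    protein_score_sd: float = 15.0
    contaminant_high_score_fraction: float = 0.5
    mod_probability: float = 0.1
    utr_max_nt: int = 60
    truncated_fraction: float = 0.25
    min_guaranteed_spectra: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.mass_range_kda
        max_block = max((len(u) * c for u, c in self.repeat_library), default=0)
        if hi * 1000 / _AVG_RESIDUE_DA < max_block + 10:
            raise ValueError(
                "mass range too small for the repeat library "
                f"(no protein can hold a {max_block}-residue repeat block)"
            )
        if not 0 <= self.truncated_fraction <= 1:
            raise ValueError("truncated_fraction must be in [0, 1]")


@dataclass
class PlantedProtein:
    family: str
    variant_index: int
    precursor: str          # full translated sequence (signal + mature)
    signal_len: int         # 0 for contaminants
    is_contaminant: bool
    planted_repeat: tuple[str, int] | None = None
    transcript_id: str = ""
    frame: str = "+1"
    truncated_nt: int = 0   # 5' nucleotides removed from the transcript
    transcript_nt: str = ""

    @property
    def mature(self) -> str:
        return self.precursor[self.signal_len:]

    @property
    def mature_mass_kda(self) -> float:
        # quick average-mass estimate used for band windowing
        return (len(self.mature) * _AVG_RESIDUE_DA + 18.0) / 1000.0

    @property
    def isoform_id(self) -> str:
        return f"{self.transcript_id}|{self.frame}"


@dataclass
class SyntheticTruth:
    proteins: list[PlantedProtein]
    psm_plan: dict[str, dict[str, int]]  # isoform_id -> sample -> planned count
    seed: int
    config: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def secreted(self) -> list[PlantedProtein]:
        return [p for p in self.proteins if not p.is_contaminant]

    @property
    def contaminants(self) -> list[PlantedProtein]:
        return [p for p in self.proteins if p.is_contaminant]


def _choice(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(rng.choice(list(pool), size=n))


def _make_signal(rng: np.random.Generator) -> str:
    """n/h/c signal peptide that satisfies the cleavage heuristic."""
    n_region = "MK" + _choice(rng, "NQST", int(rng.integers(0, 3)))
    h_region = _choice(rng, _HYDROPHOBIC, int(rng.integers(10, 14)))
    c_region = _choice(rng, "PQ", 1) + "ASA"  # small residues at -3/-1
    return n_region + h_region + c_region


def _make_mature(
    rng: np.random.Generator, length: int, repeat: tuple[str, int] | None
) -> str:
    seq = _choice(rng, _MATURE_POOL, length)
    if repeat is not None:
        unit, copies = repeat
        block = unit * copies
        pos = int(rng.integers(1, max(2, length - len(block))))
        seq = seq[:pos] + block + seq[pos + len(block):]
        # re-draw flanks that would extend the planted run by a unit
        for _ in range(20):
            left = seq[max(0, pos - len(unit)):pos]
            right = seq[pos + len(block):pos + len(block) + len(unit)]
            if left != unit and right != unit:
                break
            seq = seq[:pos] + block + _choice(rng, _MATURE_POOL,
                                              len(seq) - pos - len(block))
        seq = seq[:length] if len(seq) >= length else seq
    return seq


def simulate_proteome(
    config: SimulationConfig | None = None, seed: int = 0
) -> SyntheticTruth:
    """Plant secreted byssal-like protein families and contaminants."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.mass_range_kda
    proteins: list[PlantedProtein] = []
    for f in range(config.n_families):
        family = f"Sfp{f + 1}"
        signal = _make_signal(rng)
        target_kda = float(rng.uniform(lo, hi))
        length = max(30, int(target_kda * 1000 / _AVG_RESIDUE_DA))
        repeat = None
        if rng.random() < config.repeat_probability:
            fitting = [r for r in config.repeat_library
                       if len(r[0]) * r[1] + 10 <= length]
            if fitting:
                repeat = fitting[int(rng.integers(len(fitting)))]
        base = _make_mature(rng, length, repeat)
        for v in range(config.variants_per_family):
            mature = base
            if v > 0:
                # splicing-like internal deletion in the C-terminal half
                span = int(rng.integers(4, 12)) * (v)
                cut = int(rng.integers(len(base) // 2, max(len(base) - span, len(base) // 2) + 1))
                mature = base[:cut] + base[cut + span:]
            proteins.append(
                PlantedProtein(
                    family=family,
                    variant_index=v,
                    precursor=signal + mature,
                    signal_len=len(signal),
                    is_contaminant=False,
                    planted_repeat=repeat if v == 0 else None,
                )
            )
    for c in range(config.n_contaminants):
        family = f"Contam{c + 1}"
        target_kda = float(rng.uniform(lo, hi))
        length = max(30, int(target_kda * 1000 / _AVG_RESIDUE_DA))
        # acidic N-terminus so the signal heuristic cannot fire
        seq = "MDDE" + _choice(rng, _CONTAM_POOL, length - 4)
        proteins.append(
            PlantedProtein(
                family=family, variant_index=0, precursor=seq,
                signal_len=0, is_contaminant=True,
            )
        )
    truth = SyntheticTruth(proteins=proteins, psm_plan={}, seed=seed, config=config)
    _reverse_translate_all(truth, rng)
    _plan_psms(truth)
    return truth


def reverse_translate(
    protein: str, seed: int | np.random.Generator = 0,
    utr_max_nt: int = 60, truncate_nt: int = 0,
) -> tuple[str, int]:
    """Encode a protein as a transcript with seeded codon choice.

    Returns ``(nucleotide_sequence, orf_offset)`` where the offset is
    the 0-based position of the first codon.  The coding sequence is
    framed by a stop codon on each side so six-frame ORF extraction
    recovers exactly the planted sequence; ``truncate_nt`` removes the
    transcript 5' end including UTR, the framing stop and the first
    coding nucleotides (emulating incomplete assembly).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cds = "".join(
        _BACK_TABLE[aa][int(rng.integers(len(_BACK_TABLE[aa])))] for aa in protein
    )
    utr5 = _choice(rng, "ACGT", int(rng.integers(0, utr_max_nt + 1)))
    utr3 = _choice(rng, "ACGT", int(rng.integers(0, utr_max_nt + 1)))
    stop5 = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    stop3 = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    seq = utr5 + stop5 + cds + stop3 + utr3
    offset = len(utr5) + 3
    if truncate_nt:
        cut = min(truncate_nt, offset + len(cds) - 3)
        seq = seq[cut:]
        offset -= cut
    return seq, offset


def _reverse_translate_all(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    families: dict[str, int] = {}
    for p in truth.proteins:
        fidx = families.setdefault(p.family, len(families))
        p.transcript_id = f"comp{1000 + fidx}_c0_seq{p.variant_index + 1}"
        truncate_aa = 0
        if (not p.is_contaminant and p.variant_index > 0
                and rng.random() < truth.config.truncated_fraction):
            # cut into the signal-encoding region: keeps the mature
            # sequence intact but removes the start codon; at least 10
            # signal residues remain so a full-signal variant can
            # complete the N-terminus by exact overlap
            truncate_aa = int(rng.integers(2, max(3, p.signal_len - 10)))
        nt, offset = reverse_translate(p.precursor, rng, truth.config.utr_max_nt)
        if truncate_aa:
            cut = offset + 3 * truncate_aa
            nt, offset, p.truncated_nt = nt[cut:], 0, cut
        p.frame = f"+{offset % 3 + 1}"
        p.transcript_nt = nt


def _plan_psms(truth: SyntheticTruth) -> None:
    cfg = truth.config
    for p in truth.proteins:
        plan: dict[str, int] = {"whole_TP": cfg.psms_per_sample}
        for band, (lo, hi) in BAND_WINDOWS.items():
            plan[band] = cfg.psms_per_sample if lo <= p.mature_mass_kda <= hi else 0
        truth.psm_plan[p.isoform_id] = plan


def _mark_modifications(
    rng: np.random.Generator, peptide: str, probability: float
) -> str:
    out = list(peptide)
    for i, c in enumerate(out):
        if c in "NQY" and rng.random() < probability:
            out[i] = c.lower()
    return "".join(out)


def _shuffled_decoy(
    rng: np.random.Generator, peptide: str, targets_il: list[str]
) -> str | None:
    letters = list(peptide)
    for _ in range(50):
        rng.shuffle(letters)
        decoy = "".join(letters)
        folded = decoy.replace("I", "L")
        if all(folded not in t for t in targets_il):
            return decoy
    return None


def simulate_psms(
    truth: SyntheticTruth,
    config: SimulationConfig | None = None,
    seed: int = 0,
    digest_params: DigestParams | None = None,
) -> pd.DataFrame:
    """Per-sample PSM tables for a planted truth.

    True peptides are drawn from tryptic digests of the planted mature
    sequences with scores ~ N(35, 8) truncated at 0 (the first
    ``min_guaranteed_spectra`` whole-extract PSMs of each planted
    protein are guaranteed to clear the peptide-score threshold);
    noise PSMs are residue-shuffled true peptides with scores
    ~ N(10, 5).  Gel-band samples only see proteins whose mature mass
    falls inside the band window.
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    digest_params = digest_params or DigestParams(missed_cleavages=1, min_len=5, max_len=60)
    rows = []
    targets_il = [p.precursor.replace("I", "L") for p in truth.proteins]
    for p in truth.proteins:
        peptides = [pep for pep, _ in digest(p.mature, digest_params)]
        if not peptides:
            continue
        if p.is_contaminant:
            high = rng.random() < config.contaminant_high_score_fraction
            prot_score = (
                max(55.0, float(rng.normal(70, 10))) if high
                else min(49.0, max(5.0, float(rng.normal(35, 8))))
            )
        else:
            prot_score = max(55.0, float(rng.normal(
                config.protein_score_mu, config.protein_score_sd)))
        for sample, n_psms in truth.psm_plan[p.isoform_id].items():
            for k in range(n_psms):
                pep = peptides[int(rng.integers(len(peptides)))]
                score = max(0.0, float(rng.normal(
                    config.true_score_mu, config.true_score_sd)))
                if (sample == "whole_TP" and not p.is_contaminant
                        and k < config.min_guaranteed_spectra):
                    score = max(score, 20.0)
                rows.append({
                    "sample": sample,
                    "peptide": _mark_modifications(rng, pep, config.mod_probability),
                    "peptide_score": round(score, 2),
                    "alc": "",
                    "is_de_novo_only": False,
                    "protein_score": round(prot_score, 2),
                    "transcript_hint": p.transcript_id,
                })
    # noise: shuffled decoys, low scores, some purely de novo
    true_peps = [r["peptide"].upper() for r in rows]
    for _ in range(config.n_noise_psms):
        if not true_peps:
            break
        base = true_peps[int(rng.integers(len(true_peps)))]
        decoy = _shuffled_decoy(rng, base, targets_il)
        if decoy is None:
            continue
        de_novo = rng.random() < 0.5
        rows.append({
            "sample": SAMPLES[int(rng.integers(len(SAMPLES)))],
            "peptide": decoy,
            "peptide_score": round(max(0.0, float(rng.normal(
                config.noise_score_mu, config.noise_score_sd))), 2),
            "alc": round(float(rng.uniform(40, 95)), 1) if de_novo else "",
            "is_de_novo_only": de_novo,
            "protein_score": "",
            "transcript_hint": "",
        })
    return pd.DataFrame(rows, columns=[
        "sample", "peptide", "peptide_score", "alc", "is_de_novo_only",
        "protein_score", "transcript_hint",
    ])


def write_dataset(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Emit a complete synthetic dataset under ``outdir``.

    Files: transcripts.fasta, psms_<sample>.tsv, hits.tsv, classes.tsv,
    signals.tsv, truth.json.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_proteome(config, seed)
    with open(outdir / "transcripts.fasta", "w") as fh:
        for p in truth.proteins:
            fh.write(f">{p.transcript_id}\n{p.transcript_nt}\n")
    psms = simulate_psms(truth, config, seed=seed + 1)
    for sample in SAMPLES:
        sub = psms[psms["sample"] == sample]
        sub.to_csv(outdir / f"psms_{sample}.tsv", sep="\t", index=False)
    psms.to_csv(outdir / "psms_all.tsv", sep="\t", index=False)
    # homology table: every contaminant hits a known cellular protein
    # well below the E-value cutoff; one secreted family hits a known
    # byssal homolog (allowlisted, must not reject)
    hit_rows = []
    classes = {}
    rng = np.random.default_rng(seed + 2)
    for i, p in enumerate(truth.contaminants):
        subject = f"cellular_protein_{i + 1}"
        classes[subject] = "contaminant_db"
        hit_rows.append([p.isoform_id, subject, 95.0, len(p.precursor), 3, 0,
                         1, len(p.precursor), 1, len(p.precursor),
                         float(f"{rng.uniform(1e-40, 1e-10):.2e}"), 200.0])
    if truth.secreted:
        p = truth.secreted[0]
        classes["byssal_homolog_1"] = "byssal_allowlist"
        hit_rows.append([p.isoform_id, "byssal_homolog_1", 80.0,
                         len(p.mature), 10, 1, 1, len(p.mature), 1,
                         len(p.mature), 2e-66, 150.0])
    pd.DataFrame(hit_rows).to_csv(outdir / "hits.tsv", sep="\t",
                                  index=False, header=False)
    pd.DataFrame(
        sorted(classes.items()), columns=["subject", "subject_class"]
    ).to_csv(outdir / "classes.tsv", sep="\t", index=False)
    # signal annotations for non-truncated secreted proteins
    sig_rows = []
    for p in truth.secreted:
        if p.truncated_nt == 0:
            sig_rows.append({"transcript_id": p.transcript_id,
                             "cleavage_pos": p.signal_len})
    pd.DataFrame(sig_rows).to_csv(outdir / "signals.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "config": dataclasses.asdict(config),
                "proteins": [
                    {k: v for k, v in dataclasses.asdict(p).items()}
                    | {"isoform_id": p.isoform_id, "mature": p.mature}
                    for p in truth.proteins
                ],
                "psm_plan": truth.psm_plan,
            },
            fh, indent=1, default=str,
        )
    return truth
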