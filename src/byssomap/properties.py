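"""Physicochemical characterization of mature proteins.

Average mass, Henderson–Hasselbalch net charge and isoelectric point,
amino-acid composition (mol%), Kyte–Doolittle hydropathy profiles, the
compositional category used for byssal proteins (G/Y-rich, P-rich,
C-rich), terminal-segment pIs for block-structure analysis, and a
charge–hydropathy disorder proxy.

All properties are computed on the mature sequence (signal peptide
removed); the charge model treats Cys and Tyr as ionizable, matching
pepstats conventions, with a toggle for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight

from .scales import EMBOSS, KYTE_DOOLITTLE, STANDARD_AA, PKaSet
from .transcriptome import ProteinIsoform

WATER_AVG = 18.0153

CATEGORIES = ("GY_rich", "P_rich", "C_rich", "uncategorized")


@dataclass
class PropertyProfile:
    """Table-style physicochemical profile of one mature protein."""

    mature_len: int
    avg_mass_kda: float
    pI: float
    charge_at_pH7: float
    molpct: dict[str, float]
    hydropathy: np.ndarray
    category: str
    nterm_segment_pI: float | None = None
    cterm_segment_pI: float | None = None
    disorder_prone: bool | None = None
    immature_properties: bool = False


def mature_sequence(isoform: ProteinIsoform) -> tuple[str, bool]:
    """Mature sequence of an isoform and a flag for missing annotation.

    Returns ``(sequence_after_cleavage, immature)`` where ``immature``
    is True when no signal annotation exists and the full sequence is
    returned as-is.
    """
    if isoform.signal is None:
        return isoform.aa_sequence, True
    cut = isoform.signal.cleavage_pos
    if cut >= len(isoform.aa_sequence):
        raise ValueError("cleavage site beyond sequence length")
    return isoform.aa_sequence[cut:], False


def _check_standard(seq: str) -> None:
    bad = [i + 1 for i, c in enumerate(seq) if c not in STANDARD_AA]
    if bad:
        raise ValueError(f"non-standard residues at positions {bad}")


def average_mass(seq: str, monoisotopic: bool = False) -> float:
    """Average (default) or monoisotopic mass of a peptide in kDa."""
    if not seq:
        raise ValueError("empty sequence")
    _check_standard(seq)
    return molecular_weight(seq, seq_type="protein", monoisotopic=monoisotopic) / 1000.0


def net_charge(
    seq: str,
    pH: float = 7.0,
    pka: PKaSet = EMBOSS,
    free_termini: bool = True,
    cys_tyr_ionizable: bool = True,
) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at a pH.

    Positive groups: free N-terminus, K, R, H.  Negative groups: free
    C-terminus, D, E and, when ``cys_tyr_ionizable``, C and Y.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError("pH outside (0, 14)")
    pos = 0.0
    neg = 0.0
    if free_termini:
        pos += 1.0 / (1.0 + 10.0 ** (pH - pka.nterm))
        neg += 1.0 / (1.0 + 10.0 ** (pka.cterm - pH))
    for res in "KRH":
        pos += seq.count(res) / (1.0 + 10.0 ** (pH - getattr(pka, res)))
    negative = "DECY" if cys_tyr_ionizable else "DE"
    for res in negative:
        neg += seq.count(res) / (1.0 + 10.0 ** (getattr(pka, res) - pH))
    return pos - neg


def isoelectric_point(
    seq: str,
    pka: PKaSet = EMBOSS,
    cys_tyr_ionizable: bool = True,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH under this model, so the
    root is unique; bisection runs until the interval is < ``tol`` pH
    units (well below 1e-3).
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka, cys_tyr_ionizable=cys_tyr_ionizable) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def composition_molpct(seq: str) -> dict[str, float]:
    """Per-residue mol% over the 20 standard residues (absent -> 0)."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    return {aa: 100.0 * seq.count(aa) / n for aa in STANDARD_AA}


def hydropathy_profile(seq: str, window: int = 9) -> np.ndarray:
    """Sliding-window mean of the Kyte–Doolittle scale (no padding).

    Output length is ``len(seq) - window + 1``.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = np.array([KYTE_DOOLITTLE[c] for c in seq], dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def categorize(molpct: dict[str, float]) -> str:
    """Compositional category of a byssal protein.

    Decision rule: C-rich when C >= 10 mol%; else G/Y-rich when
    G >= 15 and Y >= 10; else P-rich when P >= 8.5 or P is the single
    most abundant residue; else uncategorized.
    """
    g = molpct.get("G", 0.0)
    y = molpct.get("Y", 0.0)
    p = molpct.get("P", 0.0)
    c = molpct.get("C", 0.0)
    if c >= 10.0:
        return "C_rich"
    if g >= 15.0 and y >= 10.0:
        return "GY_rich"
    top = max(molpct.values())
    p_is_unique_max = p == top and sum(1 for v in molpct.values() if v == top) == 1
    if p >= 8.5 or p_is_unique_max:
        return "P_rich"
    return "uncategorized"


def segment_pI(
    seq: str, n_len: int = 15, c_len: int = 15, pka: PKaSet = EMBOSS
) -> tuple[float, float]:
    """pI of the first ``n_len`` and last ``c_len`` residues.

    Each segment is treated as a free peptide (both termini ionizable),
    the convention used when describing acidic/basic terminal blocks.
    """
    if n_len < 1 or c_len < 1:
        raise ValueError("zero-length segment")
    if n_len + c_len > len(seq):
        raise ValueError("segments longer than sequence")
    return (
        isoelectric_point(seq[:n_len], pka),
        isoelectric_point(seq[-c_len:], pka),
    )


def charge_hydropathy_flag(seq: str, pka: PKaSet = EMBOSS) -> bool | None:
    """Uversky charge–hydropathy disorder proxy.

    Flags a sequence as disorder-prone when its mean absolute net
    charge per residue at pH 7 exceeds ``2.785 * <H> - 1.151``, where
    ``<H>`` is the mean Kyte–Doolittle hydropathy rescaled to [0, 1].
    Returns None for sequences shorter than 20 residues.
    """
    if len(seq) < 20:
        return None
    mean_abs_charge = abs(net_charge(seq, 7.0, pka)) / len(seq)
    kd = np.mean([(KYTE_DOOLITTLE[c] + 4.5) / 9.0 for c in seq])
    return mean_abs_charge > 2.785 * float(kd) - 1.151


def profile(
    isoform: ProteinIsoform,
    pka: PKaSet = EMBOSS,
    window: int = 9,
    n_len: int = 15,
    c_len: int = 15,
) -> PropertyProfile:
    """Full property profile of an isoform's mature sequence."""
    seq, immature = mature_sequence(isoform)
    molpct = composition_molpct(seq)
    nseg = cseg = None
    if n_len + c_len <= len(seq):
        nseg, cseg = segment_pI(seq, n_len, c_len, pka)
    return PropertyProfile(
        mature_len=len(seq),
        avg_mass_kda=average_mass(seq),
        pI=isoelectric_point(seq, pka),
        charge_at_pH7=net_charge(seq, 7.0, pka),
        molpct=molpct,
        hydropathy=hydropathy_profile(seq, window) if window <= len(seq) else np.array([]),
        category=categorize(molpct),
        nterm_segment_pI=nseg,
        cterm_segment_pI=cseg,
        disorder_prone=charge_hydropathy_flag(seq, pka),
        immature_properties=immature,
    )
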