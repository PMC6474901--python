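"""Residue-level scales and ionization constants.

Holds the Kyte–Doolittle hydropathy scale, pKa sets for
Henderson–Hasselbalch charge calculations, and the Greek alphabet used
to label protein variants within a family.
"""

from __future__ import annotations

from dataclasses import dataclass

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle hydropathy values (kcal/mol-ish arbitrary units).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PKaSet:
    """Ionizable-group pKa values (pH units, all in (0, 14)).

    ``nterm``/``cterm`` are the free alpha-amino and alpha-carboxyl
    groups; side chains cover the seven ionizable residues.
    """

    name: str
    nterm: float
    cterm: float
    K: float
    R: float
    H: float
    D: float
    E: float
    C: float
    Y: float

    def __post_init__(self) -> None:
        for field in ("nterm", "cterm", "K", "R", "H", "D", "E", "C", "Y"):
            v = getattr(self, field)
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {field}={v} outside (0, 14)")


#: EMBOSS (pepstats/iep) defaults; the set under which published Dbfp
#: pI values are reproducible.
EMBOSS = PKaSet("emboss", nterm=8.6, cterm=3.6,
                K=10.8, R=12.5, H=6.5, D=3.9, E=4.1, C=8.5, Y=10.1)

BJELLQVIST = PKaSet("bjellqvist", nterm=7.5, cterm=3.55,
                    K=10.0, R=12.0, H=5.98, D=4.05, E=4.45, C=9.0, Y=10.0)

LEHNINGER = PKaSet("lehninger", nterm=9.69, cterm=2.34,
                   K=10.5, R=12.4, H=6.0, D=3.86, E=4.25, C=8.3, Y=10.07)

PKA_SETS = {s.name: s for s in (EMBOSS, BJELLQVIST, LEHNINGER)}

#: Greek letters for variant labels, assigned by decreasing mature mass.
GREEK_LETTERS = (
    "αβγδεζηθ"  # alpha..theta
    "ικλμνξοπ"  # iota..pi
    "ρστυφχψω"  # rho..omega
)
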