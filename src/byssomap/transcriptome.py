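"""Transcriptome model: FASTA ingestion, six-frame translation, ORF
extraction, variant naming and assembly statistics.

Transcripts carry a Trinity-style component identity (``comp<N>_c<K>``)
so that isoforms of the same gene-like family can be grouped; variants
within a family are labelled with Greek letters by decreasing mature
mass, following the Dreissenid foot-protein naming convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

from .scales import GREEK_LETTERS

log = logging.getLogger(__name__)

_COMPONENT_RE = re.compile(r"(comp\d+_c\d+)")
_NT_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")

# Standard genetic code, codon -> one-letter residue; stops as "*".
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_CODON_TABLE.forward_table)
_CODON_MAP.update({c: "*" for c in _CODON_TABLE.stop_codons})


class FastaParseError(ValueError):
    """Raised when a transcriptome FASTA cannot be parsed."""


@dataclass(frozen=True)
class SignalAnnotation:
    """Signal-peptide cleavage site.

    ``cleavage_pos`` is the 1-based index of the LAST signal residue;
    the mature sequence starts at ``cleavage_pos + 1``.
    """

    cleavage_pos: int
    source: str  # one of {"annotation_file", "heuristic", "variant_completion"}

    def __post_init__(self) -> None:
        if not 5 <= self.cleavage_pos <= 40:
            raise ValueError(
                f"cleavage_pos {self.cleavage_pos} outside plausible range 5..40"
            )


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    component_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        if not self.component_id:
            object.__setattr__(self, "component_id", _component_of(self.id))

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinIsoform:
    """A translated ORF, possibly signal-annotated."""

    transcript_id: str
    frame: str
    aa_sequence: str
    has_start: bool = False
    has_stop: bool = False
    signal: SignalAnnotation | None = None
    family: str = ""
    variant_label: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError("isoform with empty sequence")
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame!r}")
        if self.signal is not None and self.signal.cleavage_pos >= len(self.aa_sequence):
            raise ValueError("signal cleavage site beyond sequence end")

    @property
    def isoform_id(self) -> str:
        return f"{self.transcript_id}|{self.frame}"

    @property
    def mature_start(self) -> int:
        """0-based index where the mature sequence begins."""
        return self.signal.cleavage_pos if self.signal is not None else 0


def _component_of(transcript_id: str) -> str:
    m = _COMPONENT_RE.search(transcript_id)
    if m:
        return m.group(1)
    log.debug("id %r lacks a comp<N>_c<K> prefix; singleton component", transcript_id)
    return transcript_id


def normalize_nt(seq: str) -> str:
    """Upper-case and map U->T; reject characters outside {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise FastaParseError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


def read_transcripts(fasta_source: str | Path) -> list[Transcript]:
    """Read a nucleotide FASTA into Transcript records.

    The component id is parsed from a Trinity-style ``comp<N>_c<K>``
    prefix when present; otherwise every transcript is its own
    component.
    """
    path = Path(fasta_source)
    if not path.exists():
        raise FileNotFoundError(path)
    transcripts: list[Transcript] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            seq = normalize_nt(str(rec.seq))
            transcripts.append(Transcript(id=rec.id, sequence=seq))
        except ValueError as exc:
            raise FastaParseError(f"record {i} ({rec.id!r}): {exc}") from exc
    if not transcripts:
        raise FastaParseError(f"{path}: no FASTA records found")
    return transcripts


def reverse_complement(seq: str) -> str:
    return seq.translate(_NT_COMPLEMENT)[::-1]


def _translate_frame(nt: str) -> str:
    """Translate one reading frame; any codon containing N yields X."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        aas.append(_CODON_MAP.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(t: Transcript | str) -> list[tuple[str, str]]:
    """Translate a transcript in all six reading frames.

    Returns ``[(frame, aa_string)]`` for frames +1..+3 (forward strand,
    offsets 0..2) and -1..-3 (reverse complement, offsets 0..2).  Stop
    codons appear as ``*``; trailing 1-2 nt are dropped; codons with N
    become ``X``.
    """
    seq = t.sequence if isinstance(t, Transcript) else normalize_nt(t)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(seq)
    out = []
    for offset in range(3):
        out.append((f"+{offset + 1}", _translate_frame(seq[offset:])))
    for offset in range(3):
        out.append((f"-{offset + 1}", _translate_frame(rc[offset:])))
    return out


def extract_orfs(
    frames: Sequence[tuple[str, str]],
    min_aa: int = 30,
    mode: str = "keep_all",
    transcript_id: str = "",
    family: str = "",
) -> list[ProteinIsoform]:
    """Split each frame on stop codons and keep segments >= ``min_aa``.

    ``mode="keep_all"`` retains segments without a leading Met (the
    default: several byssal proteins were recovered without start
    codons); ``mode="require_start"`` trims each segment to its first M
    and drops M-less segments.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if mode not in ("keep_all", "require_start"):
        raise ValueError(f"unknown ORF mode {mode!r}")
    isoforms: list[ProteinIsoform] = []
    for frame, aa in frames:
        segments = aa.split("*")
        for i, seg in enumerate(segments):
            has_stop = i < len(segments) - 1
            if mode == "require_start":
                m = seg.find("M")
                if m < 0:
                    continue
                seg = seg[m:]
            if len(seg) < min_aa:
                continue
            isoforms.append(
                ProteinIsoform(
                    transcript_id=transcript_id,
                    frame=frame,
                    aa_sequence=seg,
                    has_start=seg.startswith("M"),
                    has_stop=has_stop,
                    family=family,
                )
            )
    return isoforms


def assign_variant_names(
    family: Sequence[ProteinIsoform], mature_masses_da: Sequence[float]
) -> list[ProteinIsoform]:
    """Label variants with Greek letters by strictly decreasing mature mass.

    Ties break by lexicographic amino-acid sequence, then transcript id.
    """
    if not family:
        raise ValueError("empty family")
    if len(family) != len(mature_masses_da):
        raise ValueError("one mass per isoform required")
    if len(family) > len(GREEK_LETTERS):
        raise ValueError(f"more than {len(GREEK_LETTERS)} variants: alphabet exhausted")
    order = sorted(
        range(len(family)),
        key=lambda i: (-mature_masses_da[i], family[i].aa_sequence, family[i].transcript_id),
    )
    labelled = list(family)
    for rank, idx in enumerate(order):
        labelled[idx] = replace_label(family[idx], GREEK_LETTERS[rank])
    return labelled


def replace_label(iso: ProteinIsoform, label: str) -> ProteinIsoform:
    out = ProteinIsoform(**{**iso.__dict__, "variant_label": label})
    return out


def complete_signal_from_variants(
    family: Sequence[ProteinIsoform], min_overlap: int = 10
) -> list[ProteinIsoform]:
    """Complete truncated N-termini from a variant with an intact signal.

    If one isoform of the family has a complete signal peptide
    (``has_start`` and a signal annotation) and an incomplete isoform's
    N-terminal region overlaps the donor's N-terminal region exactly
    over >= ``min_overlap`` residues, the incomplete isoform is extended
    with the donor's prefix and annotated with
    ``source="variant_completion"``.
    """
    donors = [f for f in family if f.has_start and f.signal is not None]
    out: list[ProteinIsoform] = []
    for iso in family:
        if iso.has_start or iso.signal is not None or not donors:
            out.append(iso)
            continue
        completed = None
        for donor in donors:
            dseq = donor.aa_sequence
            # acceptor must begin somewhere inside the donor signal
            # region with an exact overlap of >= min_overlap residues;
            # only the signal region is compared because mature regions
            # of variants may legitimately diverge
            limit = min(len(dseq), donor.signal.cleavage_pos)
            for start in range(1, limit):
                overlap = min(limit - start, len(iso.aa_sequence))
                if overlap < min_overlap:
                    break
                if dseq[start:start + overlap] == iso.aa_sequence[:overlap]:
                    new_seq = dseq[:start] + iso.aa_sequence
                    completed = ProteinIsoform(
                        transcript_id=iso.transcript_id,
                        frame=iso.frame,
                        aa_sequence=new_seq,
                        has_start=donor.has_start,
                        has_stop=iso.has_stop,
                        signal=SignalAnnotation(
                            donor.signal.cleavage_pos, "variant_completion"
                        ),
                        family=iso.family,
                        variant_label=iso.variant_label,
                    )
                    break
            if completed:
                break
        if completed is None:
            log.warning(
                "no signal completion for %s (overlap < %d or mismatch)",
                iso.isoform_id, min_overlap,
            )
            out.append(iso)
        else:
            out.append(completed)
    return out


def assembly_stats(transcripts: Sequence[Transcript]) -> dict:
    """Summary statistics of an assembly: counts, median, N50, N30.

    Nxx is the length L such that contigs of length >= L together
    contain at least xx% of all assembled bases.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    lengths = sorted((t.length_bp for t in transcripts), reverse=True)
    total = sum(lengths)

    def nxx(frac: float) -> int:
        cum = 0
        for length in lengths:
            cum += length
            if cum >= frac * total:
                return length
        return lengths[-1]

    n = len(lengths)
    mid = n // 2
    median = (lengths[mid] if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2)
    return {
        "n_transcripts": n,
        "n_components": len({t.component_id for t in transcripts}),
        "median_bp": median,
        "N50_bp": nxx(0.50),
        "N30_bp": nxx(0.30),
    }
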