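"""Exact tandem-repeat detection and degenerate-motif counting.

Byssal proteins are characterized by short exact tandem repeats (e.g.
the octapeptide PKYPGGGN) and degenerate consensus motifs written in
alternation notation such as ``YP(T/D)Y(P/T)EKK`` with ``x`` as a
wildcard.  Repeats are matched exactly; sequence variation is expressed
at the motif layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RepeatHit:
    """A maximal run of exact consecutive copies of a unit.

    ``start`` is 1-based; the covered span is
    ``[start, start + unit_len * copies)``.
    """

    unit: str
    copies: int
    start: int

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def end(self) -> int:
        """1-based exclusive end of the covered span."""
        return self.start + self.unit_len * self.copies


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: per-position allowed residue sets.

    ``positions`` is a tuple of residue strings; a one-character string
    is a fixed position, longer strings are alternations in the order
    they should be rendered (``(Y/S)`` style).
    """

    positions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("empty pattern")
        if any(not p for p in self.positions):
            raise ValueError("empty alternation in pattern")

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, fragment: str) -> bool:
        return len(fragment) == len(self.positions) and all(
            c in allowed for c, allowed in zip(fragment, self.positions)
        )

    def to_text(self) -> str:
        out = []
        for p in self.positions:
            out.append(p if len(p) == 1 else "(" + "/".join(p) + ")")
        return "".join(out)


class PatternError(ValueError):
    """Raised on malformed motif notation; carries the 1-based column."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


def find_tandem_repeats(
    seq: str, min_unit: int = 2, max_unit: int = 12, min_copies: int = 2
) -> list[RepeatHit]:
    """All maximal exact tandem repeats with unit length in a range.

    For each unit length the sequence is scanned for maximal periodic
    regions; within a region, every phase (rotation of the unit) that
    achieves the region's maximal copy count is reported, so a run is
    never extendable by a full unit on either side.  Runs wholly
    explained by a shorter-unit run over the same span (e.g. ABAB x2
    inside AB x4) are suppressed.  Results are sorted by start
    position, then unit length.
    """
    if min_unit < 1 or max_unit < min_unit:
        raise ValueError("invalid unit-length range")
    n = len(seq)
    hits: list[RepeatHit] = []
    for u in range(min_unit, min(max_unit, n // min_copies) + 1):
        i = 0
        while i + u < n:
            if seq[i + u] != seq[i]:
                i += 1
                continue
            # maximal u-periodic region starting at i
            k = i + u
            while k < n and seq[k] == seq[k - u]:
                k += 1
            c_max = (k - i) // u
            if c_max >= min_copies:
                # phases achieving c_max full copies within the region
                last_phase = min(i + u - 1, k - u * c_max)
                for p in range(i, last_phase + 1):
                    hits.append(
                        RepeatHit(unit=seq[p:p + u], copies=c_max, start=p + 1)
                    )
            # the next maximal region must start after the failing pair
            # at k, i.e. at or beyond k - u + 1
            i = k - u + 1
    return _suppress_nested(sorted(hits, key=lambda h: (h.start, h.unit_len)))


def _suppress_nested(hits: list[RepeatHit]) -> list[RepeatHit]:
    kept: list[RepeatHit] = []
    for h in hits:
        explained = any(
            s.unit_len < h.unit_len
            and h.unit_len % s.unit_len == 0
            and s.start <= h.start
            and s.end >= h.end
            for s in hits
            if s is not h
        )
        if not explained:
            kept.append(h)
    return kept


def parse_pattern(text: str) -> MotifPattern:
    """Parse ``YP(T/D)Y(P/T)EKK``-style notation into a MotifPattern.

    ``x`` (either case) is a wildcard matching any of the 20 standard
    residues; parenthesized groups are ``/``-separated alternations.
    """
    positions: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j < 0:
                raise PatternError("unbalanced parenthesis", i + 1)
            body = text[i + 1:j]
            residues = body.split("/")
            if not body or any(len(r) != 1 for r in residues):
                raise PatternError(f"malformed alternation {body!r}", i + 2)
            for k, r in enumerate(residues):
                if r.upper() not in STANDARD_AA:
                    raise PatternError(f"invalid residue {r!r}", i + 2 + 2 * k)
            positions.append("".join(r.upper() for r in residues))
            i = j + 1
        elif c == ")":
            raise PatternError("unbalanced parenthesis", i + 1)
        elif c in "xX":
            positions.append(STANDARD_AA)
            i += 1
        else:
            if c.upper() not in STANDARD_AA:
                raise PatternError(f"invalid residue {c!r}", i + 1)
            positions.append(c.upper())
            i += 1
    if not positions:
        raise PatternError("empty pattern", 1)
    return MotifPattern(tuple(positions))


def count_motif(
    seq: str, pattern: MotifPattern | str, allow_overlap: bool = True
) -> tuple[int, list[int]]:
    """Count motif occurrences; returns ``(count, 1-based starts)``.

    Overlapping occurrences are counted by default (required, e.g., for
    GNYG runs sharing a glycine).
    """
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    m = len(pattern)
    if m > len(seq):
        return 0, []
    starts: list[int] = []
    i = 0
    while i + m <= len(seq):
        if pattern.matches(seq[i:i + m]):
            starts.append(i + 1)
            i += 1 if allow_overlap else m
        else:
            i += 1
    return len(starts), starts


def consensus_from_occurrences(occurrences: Sequence[str]) -> MotifPattern:
    """Position-wise consensus of equal-length occurrences.

    Fixed positions stay fixed; variable positions become alternations
    ordered by decreasing frequency (ties keep first-occurrence order).
    """
    if len(occurrences) < 2:
        raise ValueError("need at least two occurrences")
    length = len(occurrences[0])
    if any(len(o) != length for o in occurrences):
        raise ValueError("occurrences differ in length")
    positions = []
    for i in range(length):
        column = [o[i] for o in occurrences]
        counts = Counter(column)
        ordered = sorted(counts, key=lambda r: (-counts[r], column.index(r)))
        positions.append("".join(ordered))
    return MotifPattern(tuple(positions))
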