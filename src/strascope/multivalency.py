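"""Degenerate-motif multivalency counting and sequestration stoichiometry.

A multivalent decoy RNA carrying M binding sites at n_RNA copies per cell can
occupy at most 100 * M * n_RNA / N_prot percent of a protein pool of N_prot
copies, assuming one protein bound per site.  The upper bound uses all motif
instances; the lower bound uses only the maximal set of non-overlapping ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .motifs import normalize_rna

IUPAC_RNA = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "T": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


@dataclass(frozen=True)
class DegeneratePattern:
    """IUPAC-degenerate motif, e.g. YUCUYY with Y = {C, U}."""

    name: str
    positions: tuple[frozenset, ...]

    @classmethod
    def from_iupac(cls, pattern: str, name: str | None = None) -> "DegeneratePattern":
        pattern = pattern.upper()
        try:
            positions = tuple(IUPAC_RNA[ch] for ch in pattern)
        except KeyError as exc:
            raise ValueError(f"not an IUPAC RNA code: {exc.args[0]!r}") from exc
        if not positions:
            raise ValueError("empty pattern")
        return cls(name or pattern, positions)

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, start: int) -> bool:
        if start + len(self) > len(seq):
            return False
        return all(seq[start + i] in allowed for i, allowed in enumerate(self.positions))

    def to_regex(self) -> re.Pattern:
        """Overlap-tolerant regex (lookahead) for fast scanning."""
        body = "".join(
            next(iter(a)) if len(a) == 1 else "[" + "".join(sorted(a)) + "]"
            for a in self.positions
        )
        return re.compile(f"(?=({body}))")


# canonical PTBP1 recognition elements
PTBP1_PATTERNS = (
    DegeneratePattern.from_iupac("YUCUYY"),
    DegeneratePattern.from_iupac("YYUCUY"),
)


def count_motif_instances(
    seq: str,
    patterns: Sequence[DegeneratePattern] = PTBP1_PATTERNS,
    mode: str = "union",
) -> tuple[int, list[int]]:
    """Count pattern instances on the sense strand; overlaps allowed.

    ``mode="union"`` (default) counts a start position once if any pattern
    matches there (one physical site); ``mode="per-pattern"`` counts each
    matching (pattern, start) pair.  Returns (count, sorted unique starts).
    """
    if mode not in ("union", "per-pattern"):
        raise ValueError(f"unknown counting mode {mode!r}")
    s = normalize_rna(seq)
    starts: set[int] = set()
    per_pattern = 0
    for pat in patterns:
        pat_starts = [m.start() for m in pat.to_regex().finditer(s)]
        per_pattern += len(pat_starts)
        starts.update(pat_starts)
    positions = sorted(starts)
    count = per_pattern if mode == "per-pattern" else len(positions)
    return count, positions


def max_nonoverlapping_count(positions: Sequence[int], width: int) -> int:
    """Size of a maximum set of pairwise non-overlapping [p, p+width) sites.

    Greedy earliest-end selection, which is optimal for equal-width intervals.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    last_end = None
    count = 0
    for p in sorted(positions):
        if last_end is None or p >= last_end:
            count += 1
            last_end = p + width
    return count


def sequestration_capacity(
    motif_count: float, rna_copies_per_cell: float, protein_copies_per_cell: float
) -> float:
    """Percent of the protein pool sequestrable: 100*M*n_RNA/N_prot, capped at 100."""
    if protein_copies_per_cell <= 0:
        raise ValueError("protein copy number must be positive")
    if motif_count < 0 or rna_copies_per_cell < 0:
        raise ValueError("counts must be non-negative")
    pct = 100.0 * motif_count * rna_copies_per_cell / protein_copies_per_cell
    return min(pct, 100.0)
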