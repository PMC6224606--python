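"""Transcript-level filters and annotations for the strRNA screen.

Implements the two pre-screen filters (strand-specific exonic overlap with
known transcribed sequence; median-TPM expression floor), the intergenic
class-"u" call, longest-ORF coding potential, and STR (short tandem repeat)
content of spliced transcripts.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import normalize_rna

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon structure of one transcript (exons sorted, disjoint, same strand)."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"{self.transcript_id}: exon chromosome mismatch")

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)


@dataclass
class ScreenConfig:
    """The screen's fixed thresholds."""

    tpm_floor: float = 0.1
    z_threshold: float = 5.0
    alpha_p: float = 0.001
    f_min: float = 0.85
    str_unit_range: tuple[int, int] = (2, 12)
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.str_unit_range
        if not (2 <= lo <= hi <= 12):
            raise ValueError("str_unit_range must lie within [2, 12]")
        for name in ("tpm_floor", "z_threshold", "alpha_p", "f_min", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# interval indexing helpers
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent (start, end) pairs into disjoint ones."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class _MergedIndex:
    """Merged, sorted interval sets keyed by an arbitrary grouping key."""

    def __init__(self, grouped: Mapping[object, Iterable[tuple[int, int]]]):
        self._starts: dict[object, list[int]] = {}
        self._ends: dict[object, list[int]] = {}
        for key, ivs in grouped.items():
            merged = merge_intervals(ivs)
            self._starts[key] = [s for s, _ in merged]
            self._ends[key] = [e for _, e in merged]

    def overlap(self, key: object, start: int, end: int) -> int:
        """Total overlapped length of [start, end) with the merged set."""
        starts = self._starts.get(key)
        if not starts:
            return 0
        ends = self._ends[key]
        total = 0
        i = max(0, bisect_right(starts, start) - 1)
        while i < len(starts) and starts[i] < end:
            total += max(0, min(end, ends[i]) - max(start, starts[i]))
            i += 1
        return total

    def overlaps(self, key: object, start: int, end: int) -> bool:
        return self.overlap(key, start, end) > 0


def _group_by(intervals: Iterable[GenomicInterval], stranded: bool) -> dict:
    grouped: dict = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if stranded else iv.chrom
        grouped.setdefault(key, []).append((iv.start, iv.end))
    return grouped


# ---------------------------------------------------------------------------
# filters and classifiers
# ---------------------------------------------------------------------------

def exonic_overlap_filter(
    query: TranscriptModel, known_exons: Sequence[GenomicInterval]
) -> bool:
    """Keep a transcript iff >= 1 nt of its *exons* overlaps a known exon on
    the same strand (split semantics: intron-only overlap does not count)."""
    index = _MergedIndex(_group_by(known_exons, stranded=True))
    chroms = {iv.chrom for iv in known_exons}
    if known_exons and query.chrom not in chroms:
        logger.warning(
            "chromosome %s of %s absent from known-exon track; zero overlap",
            query.chrom,
            query.transcript_id,
        )
    key = (query.chrom, query.strand)
    return any(index.overlaps(key, e.start, e.end) for e in query.exons)


def expression_filter(tpm: pd.DataFrame, floor: float = 0.1) -> set[str]:
    """Transcripts whose median TPM across samples is at or above the floor."""
    if tpm.shape[1] < 1:
        raise ValueError("TPM table needs at least one sample column")
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values")
    medians = tpm.median(axis=1)
    return set(medians.index[medians >= floor])


def classify_intergenic(
    query: TranscriptModel, reference_loci: Sequence[GenomicInterval]
) -> str:
    """Class "u" (unknown intergenic) iff the query's genomic span overlaps no
    reference transcript span on either strand."""
    index = _MergedIndex(_group_by(reference_loci, stranded=False))
    span = query.span
    return "non-u" if index.overlaps(query.chrom, span.start, span.end) else "u"


def longest_orf(seq: str) -> int:
    """Length in amino acids of the longest complete ORF on the sense strand.

    An ORF runs from an AUG to the first in-frame stop; its length counts the
    codons from the AUG up to (not including) the stop.  Unterminated reading
    frames are ignored; with no AUG or no downstream stop the answer is 0.
    """
    s = normalize_rna(seq)
    best = 0
    for frame in range(3):
        start: int | None = None
        aa = 0
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == "AUG":
                    start = i
                    aa = 1
            else:
                if codon in STOP_CODONS:
                    best = max(best, aa)
                    start = None
                    aa = 0
                else:
                    aa += 1
    return best


def str_fraction(model: TranscriptModel, strs: Sequence[GenomicInterval]) -> float:
    """Fraction of the spliced transcript covered by (merged, strand-agnostic)
    tandem-repeat intervals."""
    index = _MergedIndex(_group_by(strs, stranded=False))
    covered = sum(index.overlap(model.chrom, e.start, e.end) for e in model.exons)
    return covered / model.spliced_length


def aggregate_str_content(
    models: Sequence[TranscriptModel], strs: Sequence[GenomicInterval]
) -> float:
    """Percent of the pooled spliced sequence covered by tandem repeats."""
    if not models:
        raise ValueError("empty transcript set")
    index = _MergedIndex(_group_by(strs, stranded=False))
    covered = sum(
        index.overlap(m.chrom, e.start, e.end) for m in models for e in m.exons
    )
    total = sum(m.spliced_length for m in models)
    return 100.0 * covered / total


def find_tandem_repeats(
    seq: str,
    unit_range: tuple[int, int] = (2, 12),
    min_copies: int = 3,
    min_span: int = 12,
) -> list[tuple[int, int]]:
    """Exact tandem-repeat finder for sequence-local annotation.

    Reports maximal runs where the sequence equals itself shifted by a unit
    length u in ``unit_range`` (so the run is a head-to-tail concatemer of a
    u-mer, partial last copy allowed), keeping runs with at least
    ``min_copies`` full copies and a span of at least ``min_span`` nt.
    Overlapping calls for different u are merged.  Only exact copies are
    detected (no mismatches or indels).  Homopolymers surface through their
    shortest unit in range (e.g. u = 2).
    """
    s = normalize_rna(seq)
    n = len(s)
    raw: list[tuple[int, int]] = []
    lo, hi = unit_range
    for u in range(lo, hi + 1):
        i = 0
        while i + u < n:
            if s[i] == s[i + u] and s[i] != "N":
                j = i
                while j + u < n and s[j + u] == s[j] and s[j] != "N":
                    j += 1
                span = j - i + u  # run of the periodicity, incl. the final unit
                if span // u >= min_copies and span >= min_span:
                    raw.append((i, i + span))
                i = j + 1
            else:
                i += 1
    return merge_intervals(raw)
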