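"""Position-weight-matrix scanning of RNA sequences with exact p-values.

The scanner mirrors the classic FIMO workflow: motifs are read as position
probability matrices (PPMs), converted to log-odds scores against a smoothed
background, and every sense-strand window of each transcript is scored.  The
null distribution of window scores is computed exactly by discretizing each
column's scores to an integer grid and convolving the per-column score
distributions under the order-0 background — the standard dynamic program for
PWM p-values.  A window is reported as a hit only if

* its p-value is below ``alpha_p`` (default 0.001), and
* its score reaches at least ``f_min`` (default 0.85) of the maximal
  achievable log-odds score ``s_max``.

All coordinates are 0-based half-open offsets within the (spliced) transcript
sequence.  Only the sense strand is scanned and no q-values are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGU"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
N_INDEX = 4


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and map T->U; unknown letters become N."""
    out = []
    for ch in seq.upper():
        if ch == "T":
            out.append("U")
        elif ch in "ACGUN":
            out.append(ch)
        else:
            out.append("N")
    return "".join(out)


def encode_rna(seq: str) -> np.ndarray:
    """Encode a normalized RNA string as int8 indices (A=0,C=1,G=2,U=3,N=4)."""
    table = np.full(256, N_INDEX, dtype=np.int8)
    for ch, idx in _BASE_INDEX.items():
        table[ord(ch)] = idx
        table[ord(ch.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class MotifFormatError(ValueError):
    """Raised when a motif file does not parse under the declared dialect."""


@dataclass
class MotifMatrix:
    """A position probability matrix over the RNA alphabet A/C/G/U.

    ``probs`` has shape (4, width); every column sums to 1.
    """

    motif_id: str
    probs: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise MotifFormatError(
                f"motif {self.motif_id!r}: probs must be a 4 x w matrix with w >= 1"
            )
        if np.any(self.probs < -1e-9) or np.any(self.probs > 1 + 1e-9):
            raise MotifFormatError(f"motif {self.motif_id!r}: probabilities outside [0, 1]")
        sums = self.probs.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
        if bad.size:
            raise MotifFormatError(
                f"motif {self.motif_id!r}: column {bad[0]} sums to {sums[bad[0]]:.6g}, not 1"
            )
        # renormalize residual rounding so downstream invariants hold to 1e-6
        self.probs = np.clip(self.probs, 0.0, 1.0)
        self.probs /= self.probs.sum(axis=0, keepdims=True)

    @property
    def width(self) -> int:
        return self.probs.shape[1]


@dataclass
class BackgroundModel:
    """Order-0/1 Markov background: base marginals and transition frequencies.

    All frequencies are strictly positive (additive smoothing is applied by
    :func:`estimate_markov1_background`).
    """

    marginal: np.ndarray
    transition: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        self.marginal = np.asarray(self.marginal, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.marginal.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("marginal must be length 4 and transition 4 x 4")
        if abs(self.marginal.sum() - 1.0) > 1e-6:
            raise ValueError("marginal frequencies must sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("every transition row must sum to 1")
        if np.any(self.marginal <= 0) or np.any(self.transition <= 0):
            raise ValueError("background frequencies must be strictly positive (smoothed)")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25), order=1)


@dataclass
class ScoringMatrix:
    """Log-odds scores (bits) for a motif against an order-0 background."""

    motif_id: str
    scores: np.ndarray  # (4, width), may contain -inf when pseudocount == 0
    s_max: float
    s_min: float
    pseudocount: float

    @property
    def width(self) -> int:
        return self.scores.shape[1]


@dataclass
class ScoreDistribution:
    """Exact discretized null distribution of window scores.

    Window scores are evaluated on the same integer grid as the null: each
    column's bit scores are rounded once (``column_scores``) and a window's
    discretized score is the sum of its per-column integers, so the p-value
    lookup is exact with respect to the discretization.  ``tail[d - offset]``
    is P(discretized score >= d) under the order-0 background.
    """

    motif_id: str
    scale: float
    offset: int
    tail: np.ndarray
    granularity: int
    column_scores: np.ndarray  # (4, width) int64 on the discretized grid

    def pvalue_discrete(self, dsum: int) -> float:
        idx = int(dsum) - self.offset
        if idx <= 0:
            return 1.0
        if idx >= self.tail.size:
            return 0.0
        return float(self.tail[idx])

    def pvalue(self, score: float) -> float:
        """p-value of an arbitrary bit score (rounded onto the grid)."""
        if not math.isfinite(score):
            return 1.0 if score < 0 else 0.0
        return self.pvalue_discrete(int(round(score * self.scale)))

    def pvalues_discrete(self, dsums: np.ndarray) -> np.ndarray:
        """Vectorized p-value lookup for discretized window scores."""
        idx = np.asarray(dsums, dtype=np.int64) - self.offset
        out = self.tail[np.clip(idx, 0, self.tail.size - 1)]
        return np.where(idx >= self.tail.size, 0.0, out)


@dataclass
class MotifHit:
    """A retained PWM match on a transcript (0-based half-open coordinates)."""

    transcript_id: str
    motif_id: str
    start: int
    end: int
    score: float
    p_value: float
    score_fraction: float


# ---------------------------------------------------------------------------
# motif file readers
# ---------------------------------------------------------------------------

def _parse_meme(text: str, path: str) -> list[MotifMatrix]:
    motifs: list[MotifMatrix] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # advance to the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability matrix"):
                j += 1
            if j == len(lines):
                raise MotifFormatError(
                    f"{path}: motif {motif_id!r} has no letter-probability matrix block"
                )
            rows = []
            j += 1
            while j < len(lines):
                row = lines[j].strip()
                if not row or row.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                fields = row.split()
                try:
                    rows.append([float(x) for x in fields[:4]])
                except ValueError:
                    break
                j += 1
            if not rows:
                raise MotifFormatError(f"{path}: motif {motif_id!r} matrix block is empty")
            probs = np.asarray(rows, dtype=float).T  # rows are positions, A C G U/T order
            motifs.append(MotifMatrix(motif_id, probs, source="meme"))
            i = j
        else:
            i += 1
    return motifs


def _parse_cisbp_tab(text: str, path: str) -> list[MotifMatrix]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MotifFormatError(f"{path}: empty CisBP matrix file")
    header = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
    cols = [c.strip().upper().replace("T", "U") for c in header]
    try:
        order = [cols.index(b) for b in "ACGU"]
    except ValueError as exc:
        raise MotifFormatError(f"{path}: CisBP header must name columns A, C, G, U/T") from exc
    rows = []
    for ln in lines[1:]:
        fields = ln.split("\t") if "\t" in ln else ln.split()
        rows.append([float(fields[k]) for k in order])
    if not rows:
        raise MotifFormatError(f"{path}: CisBP matrix has a header but no rows")
    motif_id = Path(path).stem
    return [MotifMatrix(motif_id, np.asarray(rows).T, source="cisbp-tab")]


def read_motif_matrices(path: str | Path, fmt: str = "meme") -> list[MotifMatrix]:
    """Read motifs from a minimal MEME file or a CisBP-style tab matrix.

    DNA-alphabet matrices are accepted; the T column is interpreted as U.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise MotifFormatError(f"{path}: empty motif file")
    if fmt == "meme":
        motifs = _parse_meme(text, str(path))
    elif fmt in ("cisbp", "cisbp-tab"):
        motifs = _parse_cisbp_tab(text, str(path))
    else:
        raise ValueError(f"unknown motif format {fmt!r}")
    if not motifs:
        raise MotifFormatError(f"{path}: no motifs found")
    return motifs


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------

def estimate_markov1_background(sequences: Iterable[str]) -> BackgroundModel:
    """Estimate a first-order Markov background from RNA sequences.

    Single-strand counting only (no reverse complement); T is mapped to U and
    N is skipped (a transition across an N is not counted).  One pseudo-count
    is added to every base and every transition before normalization, so all
    frequencies are strictly positive.
    """
    base_counts = np.zeros(4, dtype=np.int64)
    trans_counts = np.zeros((4, 4), dtype=np.int64)
    any_counted = False
    for seq in sequences:
        x = encode_rna(normalize_rna(seq))
        valid = x != N_INDEX
        if valid.any():
            any_counted = True
            base_counts += np.bincount(x[valid], minlength=5)[:4]
        if x.size >= 2:
            a, b = x[:-1], x[1:]
            ok = (a != N_INDEX) & (b != N_INDEX)
            if ok.any():
                np.add.at(trans_counts, (a[ok], b[ok]), 1)
    if not any_counted:
        raise ValueError("no countable A/C/G/U characters in input sequences")
    marginal = (base_counts + 1) / (base_counts.sum() + 4)
    trans = trans_counts + 1
    transition = trans / trans.sum(axis=1, keepdims=True)
    return BackgroundModel(marginal, transition, order=1)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def build_log_odds(
    matrix: MotifMatrix, background: BackgroundModel, pseudocount: float = 0.1
) -> ScoringMatrix:
    """Convert a PPM into log2-odds scores against the background marginal.

    Probabilities are regularized as p' = (p + a*q_b) / (1 + a) with the
    background-proportional pseudocount a before taking log2(p'/q_b); the
    p-value null and the scores both use the order-0 marginal q_b.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    q = background.marginal
    if np.any(q <= 0):
        raise ValueError("background marginal contains zeros; smooth it first")
    p = (matrix.probs + pseudocount * q[:, None]) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log2(p / q[:, None])
    s_max = float(scores.max(axis=0).sum())
    s_min = float(scores.min(axis=0).sum())
    return ScoringMatrix(matrix.motif_id, scores, s_max, s_min, pseudocount)


def score_pvalue_distribution(
    scoring: ScoringMatrix, background: BackgroundModel, granularity: int = 1000
) -> ScoreDistribution:
    """Exact null distribution of window scores by per-column convolution.

    Each column's four scores are rounded onto an integer grid with about
    ``granularity`` levels across the widest column; the distributions of the
    per-column scores under the order-0 background are then convolved.  Scores
    of -inf (possible at pseudocount 0) are mapped to a sentinel level placed
    below every all-finite sum, so the tail is exact for all finite scores.
    """
    if granularity < 10:
        raise ValueError("granularity must be >= 10")
    scores = scoring.scores
    q = background.marginal
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise ValueError("scoring matrix has no finite scores")
    col_span = np.where(
        np.isfinite(scores).any(axis=0),
        np.nanmax(np.where(np.isfinite(scores), scores, np.nan), axis=0)
        - np.nanmin(np.where(np.isfinite(scores), scores, np.nan), axis=0),
        0.0,
    )
    max_span = float(np.max(col_span)) if col_span.size else 0.0
    scale = granularity / max_span if max_span > 0 else 1.0

    d = np.rint(scores * scale)
    fin_mask = np.isfinite(scores)
    w = scoring.width
    # sentinel low enough that any sum containing it stays below all-finite sums
    lo_fin = d[fin_mask].min()
    hi_fin = d[fin_mask].max()
    sentinel = lo_fin - (hi_fin - lo_fin + 1) * w - granularity
    di = np.where(fin_mask, d, sentinel).astype(np.int64)

    dist = {0: 1.0}
    for i in range(w):
        nxt: dict[int, float] = {}
        for b in range(4):
            step = int(di[b, i])
            qb = q[b]
            for s, pmass in dist.items():
                key = s + step
                nxt[key] = nxt.get(key, 0.0) + pmass * qb
        dist = nxt
    levels = np.array(sorted(dist))
    masses = np.array([dist[s] for s in levels])
    offset = int(levels[0])
    dense = np.zeros(int(levels[-1]) - offset + 1)
    dense[levels - offset] = masses
    tail = np.cumsum(dense[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(scoring.motif_id, scale, offset, tail, granularity, di)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def window_scores(seq_idx: np.ndarray, scoring: ScoringMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Score every window; returns (scores, valid) where invalid windows contain N."""
    w = scoring.width
    n_windows = seq_idx.size - w + 1
    if n_windows <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores_ext = np.vstack([scoring.scores, np.zeros(w)])  # row 4 = N placeholder
    total = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for i in range(w):
        col = seq_idx[i : i + n_windows]
        valid &= col != N_INDEX
        total += scores_ext[col, i]
    total[~valid] = -np.inf
    return total, valid


def scan_sequence(
    seq: str,
    scoring: ScoringMatrix,
    dist: ScoreDistribution,
    alpha_p: float = 0.001,
    f_min: float = 0.85,
    transcript_id: str = "",
    fraction_mode: str = "logodds",
) -> list[MotifHit]:
    """Scan the sense strand of ``seq``; return retained hits sorted by start.

    Windows containing N are skipped.  ``fraction_mode`` selects how the
    0.85-of-maximum filter is normalized: ``"logodds"`` uses score/s_max
    (defined only for s_max > 0; windows with score <= 0 never pass), while
    ``"minmax"`` uses (score - s_min)/(s_max - s_min).
    """
    if fraction_mode not in ("logodds", "minmax"):
        raise ValueError(f"unknown fraction_mode {fraction_mode!r}")
    x = encode_rna(normalize_rna(seq))
    w = scoring.width
    if x.size < w:
        return []
    if fraction_mode == "logodds" and scoring.s_max <= 0:
        logger.warning(
            "motif %s has non-positive maximal score (%.4g); no hits can be emitted",
            scoring.motif_id,
            scoring.s_max,
        )
        return []
    total, valid = window_scores(x, scoring)
    if fraction_mode == "logodds":
        with np.errstate(invalid="ignore"):
            frac = total / scoring.s_max
    else:
        span = scoring.s_max - scoring.s_min
        if span <= 0:
            logger.warning("motif %s has zero score span; no hits emitted", scoring.motif_id)
            return []
        frac = (total - scoring.s_min) / span
    keep = valid & (frac >= f_min)
    if not keep.any():
        return []
    # p-values from the discretized window scores (same grid as the null)
    n_windows = total.size
    dsum = np.zeros(n_windows, dtype=np.int64)
    col_ext = np.vstack([dist.column_scores, np.zeros(w, dtype=np.int64)])
    for i in range(w):
        dsum += col_ext[x[i : i + n_windows], i]
    pvals = np.ones_like(total)
    pvals[keep] = dist.pvalues_discrete(dsum[keep])
    keep &= pvals < alpha_p
    hits = [
        MotifHit(
            transcript_id=transcript_id,
            motif_id=scoring.motif_id,
            start=int(j),
            end=int(j) + w,
            score=float(total[j]),
            p_value=float(pvals[j]),
            score_fraction=float(frac[j]),
        )
        for j in np.flatnonzero(keep)
    ]
    return hits


def count_skipped_windows(seq: str, width: int) -> int:
    """Number of windows skipped because they contain an N."""
    x = encode_rna(normalize_rna(seq))
    if x.size < width:
        return 0
    n_windows = x.size - width + 1
    valid = np.ones(n_windows, dtype=bool)
    for i in range(width):
        valid &= x[i : i + n_windows] != N_INDEX
    return int((~valid).sum())


def hits_to_rows(hits: Sequence[MotifHit]) -> list[dict]:
    return [
        {
            "transcript_id": h.transcript_id,
            "motif_id": h.motif_id,
            "start": h.start,
            "end": h.end,
            "score_bits": h.score,
            "p_value": h.p_value,
            "score_fraction": h.score_fraction,
        }
        for h in hits
    ]
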