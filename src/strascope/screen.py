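"""Transcriptome-wide motif-enrichment Z-score screen and 2x2 enrichment test.

For every (transcript, motif) pair the number of retained PWM hits and their
density (hits per kilobase of spliced transcript) are standardized across all
transcripts, zeros included.  A transcript is a candidate when some single
motif reaches the Z threshold (default 5) for both the count and the density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MotifHit


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def tally_motif_stats(
    hits: Sequence[MotifHit],
    lengths: Mapping[str, int],
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(transcript, motif) hit counts and densities in hits/kb.

    Emits one row for every transcript in ``lengths`` crossed with every motif
    (those seen in ``hits`` plus any listed in ``motif_ids``), so zero-count
    transcripts enter the Z-score population.
    """
    unknown = sorted({h.transcript_id for h in hits} - set(lengths))
    if unknown:
        raise KeyError(f"hits reference transcripts absent from lengths: {unknown[:5]}")
    motifs = sorted(set(motif_ids or []) | {h.motif_id for h in hits})
    transcripts = list(lengths)
    counts = {(t, m): 0 for t in transcripts for m in motifs}
    for h in hits:
        counts[(h.transcript_id, h.motif_id)] += 1
    rows = []
    for t in transcripts:
        length = lengths[t]
        for m in motifs:
            n = counts[(t, m)]
            rows.append(
                {
                    "transcript_id": t,
                    "motif_id": m,
                    "n_hits": n,
                    "length": length,
                    "density": 1000.0 * n / length,
                }
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "motif_id", "n_hits", "length", "density"]
    )


def compute_z_scores(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Standardize hit counts and densities per motif across transcripts.

    Uses the sample standard deviation (n-1 denominator); when a motif's
    counts are constant (sd = 0) its Z-scores are defined as 0 for every
    transcript rather than propagating infinities.
    """
    out = stats_df.copy()

    def _z(x: pd.Series) -> pd.Series:
        if len(x) < 2:
            raise ValueError(
                f"motif group of size {len(x)}: need at least 2 transcripts per motif"
            )
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return pd.Series(np.zeros(len(x)), index=x.index)
        return (x - x.mean()) / sd

    grouped = out.groupby("motif_id", sort=False)
    out["z_num"] = grouped["n_hits"].transform(_z)
    out["z_den"] = grouped["density"].transform(_z)
    return out


def select_candidates(results: pd.DataFrame, z_threshold: float = 5.0) -> pd.DataFrame:
    """Per-transcript candidate call with best-motif annotation.

    A transcript is a candidate iff at least one motif has BOTH z_num and
    z_den at or above the threshold (the two Z-scores must come from the same
    PWM).  The best motif maximizes z_num; ties break lexicographically.
    """
    if results.empty:
        raise ValueError("empty screen results")
    rows = []
    for t, grp in results.groupby("transcript_id", sort=True):
        passing = grp[(grp["z_num"] >= z_threshold) & (grp["z_den"] >= z_threshold)]
        ordered = grp.sort_values(["z_num", "motif_id"], ascending=[False, True])
        best = ordered.iloc[0]
        rows.append(
            {
                "transcript_id": t,
                "candidate": bool(len(passing)),
                "best_motif": best["motif_id"],
                "z_num": float(best["z_num"]),
                "z_den": float(best["z_den"]),
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table."""
    cells = np.array([[table.a, table.b], [table.c, table.d]])
    if cells.sum() == 0:
        warnings.warn("all-zero contingency table; p defined as 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(cells, alternative="two-sided")
    return float(p)
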