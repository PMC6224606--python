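"""Independent brute-force oracles used to validate the implementation.

Each function here recomputes a quantity by exhaustive enumeration or direct
definition, sharing no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_log_odds(probs: np.ndarray, marginal: np.ndarray, pseudocount: float) -> np.ndarray:
    p = (probs + pseudocount * marginal[:, None]) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(p / marginal[:, None])


def brute_pwm_scan(
    seq_idx: list[int],
    probs: np.ndarray,
    marginal: np.ndarray,
    pseudocount: float = 0.1,
    alpha_p: float = 0.001,
    f_min: float = 0.85,
):
    """Exhaustive-enumeration PWM scanner.

    Scores every window, computes each window's exact p-value by enumerating
    all 4^w words under the order-0 background, and applies the two retention
    filters.  Returns (retained starts, {start: (score, exact p)}).
    """
    scores = brute_log_odds(probs, marginal, pseudocount)
    w = probs.shape[1]
    s_max = scores.max(axis=0).sum()
    words = list(itertools.product(range(4), repeat=w))
    word_scores = np.array([sum(scores[b, i] for i, b in enumerate(word)) for word in words])
    word_probs = np.array([math.prod(marginal[b] for b in word) for word in words])
    retained = []
    details = {}
    for start in range(len(seq_idx) - w + 1):
        window = seq_idx[start : start + w]
        if any(b > 3 for b in window):
            continue
        score = sum(scores[b, i] for i, b in enumerate(window))
        pval = float(word_probs[word_scores >= score - 1e-12].sum())
        details[start] = (score, pval)
        if s_max <= 0:
            continue
        if score / s_max >= f_min and pval < alpha_p:
            retained.append(start)
    return retained, details


def brute_exact_pvalue(
    probs: np.ndarray, marginal: np.ndarray, score: float, pseudocount: float = 0.1
) -> float:
    """P(word score >= score) by enumerating all 4^w words."""
    scores = brute_log_odds(probs, marginal, pseudocount)
    w = probs.shape[1]
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        s = sum(scores[b, i] for i, b in enumerate(word))
        if s >= score - 1e-12:
            total += math.prod(marginal[b] for b in word)
    return total


def brute_exonic_overlap(query_exons, query_strand, known):
    """Per-base strand-aware membership test for split-overlap semantics."""
    known_bases = {
        (iv.chrom, pos, iv.strand) for iv in known for pos in range(iv.start, iv.end)
    }
    for e in query_exons:
        for pos in range(e.start, e.end):
            if (e.chrom, pos, query_strand) in known_bases:
                return True
    return False


def brute_longest_orf(seq: str) -> int:
    """Exhaustive scan over all AUG positions in all 3 frames."""
    stops = {"UAA", "UAG", "UGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "AUG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in stops:
                best = max(best, (j - i) // 3)
                break
            j += 3
    return best


def brute_max_independent(positions, width: int) -> int:
    """Maximum set of pairwise non-overlapping intervals by subset enumeration."""
    positions = sorted(positions)
    n = len(positions)
    best = 0
    for mask in range(1 << n):
        chosen = [positions[i] for i in range(n) if mask >> i & 1]
        if all(b - a >= width for a, b in zip(chosen, chosen[1:])):
            best = max(best, len(chosen))
    return best


def brute_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hyper(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def brute_ks_statistic(x, y) -> float:
    """sup |F_x - F_y| over all pooled thresholds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def brute_count_degenerate(seq: str, patterns: list[str]) -> tuple[int, list[int]]:
    """Direct per-position degenerate matching (Y = C/U etc.)."""
    codes = {
        "A": "A", "C": "C", "G": "G", "U": "U",
        "Y": "CU", "R": "AG", "N": "ACGU", "W": "AU", "S": "CG", "K": "GU", "M": "AC",
    }
    starts = set()
    for start in range(len(seq)):
        for pat in patterns:
            if start + len(pat) > len(seq):
                continue
            if all(seq[start + i] in codes[ch] for i, ch in enumerate(pat)):
                starts.add(start)
                break
    return len(starts), sorted(starts)


def brute_tandem_check(seq: str, start: int, end: int, unit_range=(2, 12)) -> bool:
    """Verify that [start, end) is an exact unit repetition for some unit size."""
    sub = seq[start:end]
    for u in range(unit_range[0], unit_range[1] + 1):
        if len(sub) >= 2 * u and all(sub[i] == sub[i % u] for i in range(len(sub))):
            return True
    return False
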