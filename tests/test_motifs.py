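"""PWM parsing, background estimation, log-odds scoring and exact p-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_background, random_motif
from oracles import brute_exact_pvalue, brute_pwm_scan
from strascope import (
    MotifMatrix,
    build_log_odds,
    estimate_markov1_background,
    read_motif_matrices,
    scan_sequence,
    score_pvalue_distribution,
)
from strascope.motifs import MotifFormatError, encode_rna, normalize_rna

MEME_ONE_MOTIF = """\
MEME version 4

ALPHABET= ACGU

MOTIF UC_test
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
0.010000 0.010000 0.010000 0.970000
0.010000 0.970000 0.010000 0.010000
"""

CISBP_TAB = """\
Pos\tA\tC\tG\tU
1\t0.1\t0.4\t0.1\t0.4
2\t0.05\t0.05\t0.05\t0.85
3\t0.05\t0.85\t0.05\t0.05
4\t0.05\t0.05\t0.05\t0.85
5\t0.1\t0.4\t0.1\t0.4
6\t0.1\t0.4\t0.1\t0.4
"""


class TestReaders:
    def test_meme_minimal(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_ONE_MOTIF)
        motifs = read_motif_matrices(p, "meme")
        assert len(motifs) == 1
        assert motifs[0].motif_id == "UC_test"
        assert motifs[0].width == 2
        # row order in MEME is A C G U; consensus is U then C
        assert motifs[0].probs[3, 0] == pytest.approx(0.97)
        assert motifs[0].probs[1, 1] == pytest.approx(0.97)

    def test_cisbp_tab(self, tmp_path):
        p = tmp_path / "PTBP1.txt"
        p.write_text(CISBP_TAB)
        motifs = read_motif_matrices(p, "cisbp")
        assert len(motifs) == 1
        assert motifs[0].width == 6
        assert motifs[0].probs[3, 1] == pytest.approx(0.85)

    def test_dna_alphabet_T_maps_to_U(self, tmp_path):
        p = tmp_path / "dna.txt"
        p.write_text(CISBP_TAB.replace("\tU", "\tT"))
        motifs = read_motif_matrices(p, "cisbp")
        assert motifs[0].probs[3, 1] == pytest.approx(0.85)

    def test_bad_column_sum_rejected(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(MEME_ONE_MOTIF.replace("0.970000", "0.470000"))
        with pytest.raises(MotifFormatError):
            read_motif_matrices(p, "meme")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.meme"
        p.write_text("")
        with pytest.raises(MotifFormatError):
            read_motif_matrices(p, "meme")


class TestBackground:
    def test_equal_composition_gives_uniform_marginal(self):
        bg = estimate_markov1_background(["ACGU"])
        assert np.allclose(bg.marginal, 0.25)

    def test_homopolymer_smoothed_counts(self):
        bg = estimate_markov1_background(["AAAA"])
        assert bg.marginal[0] == pytest.approx(5 / 8)  # (4+1)/(4+4)
        assert np.all(bg.marginal > 0)
        assert np.all(bg.transition > 0)

    def test_dinucleotide_transition_dominates(self):
        bg = estimate_markov1_background(["UCUCUC"])
        u = 3
        assert bg.transition[u].argmax() == 1  # U -> C most frequent

    def test_t_and_n_handling(self):
        bg_t = estimate_markov1_background(["TTTT"])
        bg_u = estimate_markov1_background(["UUUU"])
        assert np.allclose(bg_t.marginal, bg_u.marginal)
        with pytest.raises(ValueError):
            estimate_markov1_background(["NNNN"])


class TestLogOdds:
    def test_uniform_motif_uniform_background_scores_zero(self, uniform_bg):
        m = MotifMatrix("flat", np.full((4, 3), 0.25))
        sc = build_log_odds(m, uniform_bg)
        assert np.allclose(sc.scores, 0.0)
        assert sc.s_max == 0.0

    def test_deterministic_column_hand_values(self, uniform_bg):
        m = MotifMatrix("det", np.array([[1.0], [0.0], [0.0], [0.0]]))
        sc = build_log_odds(m, uniform_bg, pseudocount=0.1)
        # p' = (1 + 0.1*0.25)/1.1 and (0 + 0.025)/1.1 against q = 0.25
        assert sc.scores[0, 0] == pytest.approx(np.log2((1.025 / 1.1) / 0.25), abs=1e-9)
        assert sc.scores[0, 0] == pytest.approx(1.898, abs=1e-3)
        assert sc.scores[1, 0] == pytest.approx(-3.459, abs=1e-3)

    def test_zero_pseudocount_gives_minus_inf_but_finite_smax(self, uniform_bg):
        m = MotifMatrix("det", np.array([[1.0], [0.0], [0.0], [0.0]]))
        sc = build_log_odds(m, uniform_bg, pseudocount=0.0)
        assert np.isneginf(sc.scores[1, 0])
        assert np.isfinite(sc.s_max)


class TestScoreDistribution:
    def test_width1_best_base_pvalue(self, uniform_bg):
        m = MotifMatrix("w1", np.array([[0.7], [0.1], [0.15], [0.05]]))
        sc = build_log_odds(m, uniform_bg)
        dist = score_pvalue_distribution(sc, uniform_bg)
        assert dist.pvalue(sc.s_max) == pytest.approx(0.25)

    def test_tail_is_one_at_minimum_and_nonincreasing(self, uniform_bg):
        rng = np.random.default_rng(11)
        m = random_motif(rng, 4)
        sc = build_log_odds(m, uniform_bg)
        dist = score_pvalue_distribution(sc, uniform_bg)
        assert dist.tail[0] == pytest.approx(1.0)
        assert np.all(np.diff(dist.tail) <= 1e-12)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5])
    def test_tail_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(100 + width)
        bg = random_background(rng)
        m = random_motif(rng, width)
        sc = build_log_odds(m, bg)
        dist = score_pvalue_distribution(sc, bg)
        # every achievable word score agrees with the brute-force tail within
        # the accumulated per-column rounding (width/2 bins each direction)
        slack = (width / 2 + 0.5) / dist.scale
        import itertools

        for word in itertools.product(range(4), repeat=width):
            score = sum(sc.scores[b, i] for i, b in enumerate(word))
            p_impl = dist.pvalue(score)
            p_lo = brute_exact_pvalue(m.probs, bg.marginal, score + slack)
            p_hi = brute_exact_pvalue(m.probs, bg.marginal, score - slack)
            assert p_lo - 1e-12 <= p_impl <= p_hi + 1e-12


class TestScanSequence:
    def test_perfect_repeat_hits_alternating_starts(self, purine_bg, uc_motif):
        sc = build_log_odds(uc_motif, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        hits = scan_sequence("UCUC", sc, dist, transcript_id="t1")
        assert [h.start for h in hits] == [0, 2]
        assert all(h.score_fraction == pytest.approx(1.0) for h in hits)
        assert all(h.p_value < 0.001 for h in hits)

    def test_nonmatching_sequence_empty(self, purine_bg, uc_motif):
        sc = build_log_odds(uc_motif, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        assert scan_sequence("AAAA", sc, dist) == []

    def test_short_and_empty_sequences(self, purine_bg, uc_motif):
        sc = build_log_odds(uc_motif, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        assert scan_sequence("", sc, dist) == []
        assert scan_sequence("U", sc, dist) == []

    def test_windows_with_N_skipped(self, purine_bg, uc_motif):
        sc = build_log_odds(uc_motif, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        hits = scan_sequence("UCNUC", sc, dist)
        assert [h.start for h in hits] == [0, 3]

    def test_monotonicity_in_thresholds(self, purine_bg):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGU"), 200))
        m = random_motif(rng, 4)
        sc = build_log_odds(m, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        base = {h.start for h in scan_sequence(seq, sc, dist, 0.05, 0.5)}
        stricter_f = {h.start for h in scan_sequence(seq, sc, dist, 0.05, 0.8)}
        stricter_p = {h.start for h in scan_sequence(seq, sc, dist, 0.01, 0.5)}
        assert stricter_f <= base
        assert stricter_p <= base

    def test_determinism(self, purine_bg, uc_motif):
        sc = build_log_odds(uc_motif, purine_bg)
        dist = score_pvalue_distribution(sc, purine_bg)
        a = scan_sequence("UC" * 30, sc, dist)
        b = scan_sequence("UC" * 30, sc, dist)
        assert a == b

    def test_information_free_motif_yields_no_hits(self, uniform_bg):
        m = MotifMatrix("flat", np.full((4, 2), 0.25))
        sc = build_log_odds(m, uniform_bg)
        dist = score_pvalue_distribution(sc, uniform_bg)
        assert scan_sequence("ACGUACGU", sc, dist) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), width=st.integers(1, 5))
    def test_scan_matches_bruteforce_oracle(self, seed, width):
        """Retained hit sets equal the exhaustive-enumeration scanner,
        allowing one discretization bin of slack at the p threshold."""
        rng = np.random.default_rng(seed)
        bg = random_background(rng)
        m = random_motif(rng, width)
        seq = "".join(rng.choice(list("ACGU"), rng.integers(width, 51)))
        sc = build_log_odds(m, bg)
        dist = score_pvalue_distribution(sc, bg)
        impl = {h.start for h in scan_sequence(seq, sc, dist)}
        oracle, details = brute_pwm_scan(
            list(encode_rna(normalize_rna(seq))), m.probs, bg.marginal
        )
        slack = (width / 2 + 0.5) / dist.scale
        for start in impl ^ set(oracle):
            score, _ = details[start]
            p_lo = brute_exact_pvalue(m.probs, bg.marginal, score + slack)
            p_hi = brute_exact_pvalue(m.probs, bg.marginal, score - slack)
            assert p_lo <= 0.001 <= p_hi + 1e-12, (
                f"start {start}: disagreement not explained by discretization"
            )
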