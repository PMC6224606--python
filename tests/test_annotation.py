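"""Transcript filters, intergenic classification, ORF and STR annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_exonic_overlap, brute_longest_orf, brute_tandem_check
from strascope import (
    GenomicInterval,
    TranscriptModel,
    aggregate_str_content,
    classify_intergenic,
    exonic_overlap_filter,
    expression_filter,
    find_tandem_repeats,
    longest_orf,
    str_fraction,
)


def tx(tx_id="q", chrom="chr1", strand="+", exons=((100, 200),)):
    return TranscriptModel(
        tx_id, chrom, strand, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )


class TestExonicOverlap:
    def test_single_nt_overlap_keeps(self):
        known = [GenomicInterval("chr1", 199, 300, "+")]
        assert exonic_overlap_filter(tx(), known)

    def test_opposite_strand_drops(self):
        known = [GenomicInterval("chr1", 100, 200, "-")]
        assert not exonic_overlap_filter(tx(), known)

    def test_intron_only_overlap_drops(self):
        query = tx(exons=((100, 200), (500, 600)))
        known = [GenomicInterval("chr1", 250, 450, "+")]  # inside the intron
        assert not exonic_overlap_filter(query, known)

    def test_chrom_mismatch_is_zero_overlap(self):
        known = [GenomicInterval("chr2", 100, 200, "+")]
        assert not exonic_overlap_filter(tx(), known)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = rng.integers(1, 4)
        exons, pos = [], rng.integers(0, 50)
        for _ in range(n_ex):
            start = pos + rng.integers(0, 30)
            end = start + rng.integers(1, 40)
            exons.append((int(start), int(end)))
            pos = end + rng.integers(1, 30)
        query = tx(exons=tuple(exons), strand=strand)
        known = []
        for _ in range(rng.integers(0, 6)):
            s = int(rng.integers(0, 250))
            known.append(
                GenomicInterval(
                    "chr1" if rng.random() < 0.8 else "chr2",
                    s,
                    s + int(rng.integers(1, 50)),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        assert exonic_overlap_filter(query, known) == brute_exonic_overlap(
            query.exons, strand, known
        )


class TestExpressionFilter:
    def test_median_above_floor_keeps(self):
        tpm = pd.DataFrame([[0.05, 0.05, 0.2, 0.2, 0.2]], index=["t"])
        assert expression_filter(tpm) == {"t"}

    def test_median_zero_drops(self):
        tpm = pd.DataFrame([[0, 0, 0, 0.5, 0.5]], index=["t"])
        assert expression_filter(tpm) == set()

    def test_boundary_median_exactly_floor_keeps(self):
        tpm = pd.DataFrame([[0.1, 0.1, 0.1]], index=["t"])
        assert expression_filter(tpm, floor=0.1) == {"t"}

    def test_even_sample_count_mean_of_middle_two(self):
        tpm = pd.DataFrame([[0.0, 0.08, 0.12, 5.0]], index=["t"])
        assert expression_filter(tpm, floor=0.1) == {"t"}  # median = 0.1

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            expression_filter(pd.DataFrame([[-1.0]], index=["t"]))


class TestClassifyIntergenic:
    def test_distant_query_is_u(self):
        refs = [GenomicInterval("chr1", 5000, 6000, "+")]
        assert classify_intergenic(tx(), refs) == "u"

    def test_opposite_strand_span_overlap_is_non_u(self):
        refs = [GenomicInterval("chr1", 150, 160, "-")]
        assert classify_intergenic(tx(), refs) == "non-u"

    def test_query_in_reference_intron_is_non_u(self):
        # span semantics: reference span covers its introns
        refs = [GenomicInterval("chr1", 50, 400, "+")]
        assert classify_intergenic(tx(), refs) == "non-u"


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AUGUAA", 1),
            ("CCCCCC", 0),
            ("AAUGGCGUGAUAA", 2),  # only AUG is at offset 1: AUG GCG | UGA
            ("AUGAAAUAA", 2),
            ("AUGAAA", 0),  # unterminated
            ("", 0),
        ],
    )
    def test_examples(self, seq, expected):
        assert longest_orf(seq) == expected

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_frame_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), p=[0.3, 0.2, 0.2, 0.3], size=rng.integers(0, 120)))
        assert longest_orf(seq) == brute_longest_orf(seq)


class TestStrContent:
    def test_no_overlap_zero(self):
        assert str_fraction(tx(), []) == 0.0

    def test_full_coverage_one(self):
        strs = [GenomicInterval("chr1", 0, 500)]
        assert str_fraction(tx(), strs) == 1.0

    def test_partial_coverage(self):
        strs = [GenomicInterval("chr1", 100, 144)]
        assert str_fraction(tx(exons=((100, 200),)), strs) == pytest.approx(0.44)

    def test_aggregate_is_length_weighted(self):
        t1 = tx("a", exons=((0, 100),))
        t2 = tx("b", exons=((1000, 1100),))
        strs = [GenomicInterval("chr1", 0, 50)]
        assert aggregate_str_content([t1, t2], strs) == pytest.approx(25.0)
        fr = [str_fraction(t, strs) for t in (t1, t2)]
        lens = [t.spliced_length for t in (t1, t2)]
        weighted = 100 * sum(f * l for f, l in zip(fr, lens)) / sum(lens)
        assert aggregate_str_content([t1, t2], strs) == pytest.approx(weighted)

    def test_overlapping_strs_not_double_counted(self):
        strs = [GenomicInterval("chr1", 100, 150), GenomicInterval("chr1", 120, 160)]
        assert str_fraction(tx(exons=((100, 200),)), strs) == pytest.approx(0.6)


class TestFindTandemRepeats:
    def test_uc_repeat(self):
        assert find_tandem_repeats("UCUCUCUCUCUC") == [(0, 12)]

    def test_below_min_span_empty(self):
        assert find_tandem_repeats("ACGU") == []

    def test_homopolymer_found_via_unit_2(self):
        assert find_tandem_repeats("AAAAAAAAAAAA") == [(0, 12)]

    def test_embedded_repeat_coordinates(self):
        seq = "AGGA" + "CUG" * 5 + "AAGG"
        calls = find_tandem_repeats(seq, min_span=12)
        assert calls == [(4, 4 + 15)]

    def test_calls_are_disjoint_and_verifiable(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGU"), 200)) + "UC" * 30 + "".join(
            rng.choice(list("ACGU"), 50)
        )
        calls = find_tandem_repeats(seq)
        for (s1, e1), (s2, e2) in zip(calls, calls[1:]):
            assert e1 <= s2
        # each merged call must contain a verifiable exact repetition core
        assert any(brute_tandem_check(seq, s, e) for s, e in calls)
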