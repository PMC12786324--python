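"""JASPAR parsing, log-odds conversion and relative-score scanning.

The scanner is checked against an independent brute-force oracle that scores
every window (and its reverse complement) by direct per-position lookup.
"""

import itertools
import math

import numpy as np
import pytest

from circamotif import (
    DegenerateMatrixError,
    MotifParseError,
    PFM,
    ScanConfig,
    ScoreParams,
    parse_jaspar,
    pfm_to_pwm,
    relative_score,
    scan_pwm,
)
from circamotif.sequence_io import region_from_sequence, reverse_complement

from conftest import consensus_pfm, random_pfm, random_sequence

BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


# --- independent oracle -------------------------------------------------------


def oracle_score(pwm, word):
    return sum(pwm.weights[BASE_INDEX[b], j] for j, b in enumerate(word))


def oracle_scan(pwm, sequence, tau, both_strands=True):
    """Exhaustive per-window enumeration, independent of the scanner."""
    L, w = len(sequence), pwm.width
    out = []
    for i in range(L - w + 1):
        window = sequence[i : i + w]
        if "N" in window:
            continue
        for strand in ("+", "-") if both_strands else ("+",):
            word = window if strand == "+" else reverse_complement(window)
            raw = oracle_score(pwm, word)
            rel = (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)
            if rel >= tau:
                out.append((i - L, strand, raw, rel))
    return sorted(out, key=lambda t: (t[0], t[1]))


# --- parsing ------------------------------------------------------------------


class TestParseJaspar:
    def test_basic_record(self, toy_pfm):
        assert toy_pfm.motif_id == "M1"
        assert toy_pfm.width == 2
        np.testing.assert_array_equal(
            toy_pfm.counts, [[4, 0], [0, 4], [0, 0], [0, 0]]
        )

    def test_row_labels_drive_ordering(self):
        scrambled = ">M1 toy\nT [0 0]\nG [0 0]\nC [0 4]\nA [4 0]\n"
        pfm = parse_jaspar(scrambled)[0]
        np.testing.assert_array_equal(
            pfm.counts, [[4, 0], [0, 4], [0, 0], [0, 0]]
        )

    def test_bracketless_rows_and_multiple_records(self):
        text = ">A1 x\nA 1 2\nC 0 1\nG 3 0\nT 0 1\n>A2 y\nA [1]\nC [1]\nG [1]\nT [0]\n"
        pfms = parse_jaspar(text)
        assert [p.motif_id for p in pfms] == ["A1", "A2"]
        assert pfms[1].counts.sum() == 3  # column sum 3 accepted

    @pytest.mark.parametrize(
        "text, match",
        [
            (">M x\nA [1]\nC [1]\nG [1]\n", "missing row"),
            (">M x\nA [1 2]\nC [1]\nG [1 2]\nT [1 2]\n", "ragged"),
            (">M x\nA [1 0]\nC [1 0]\nG [1 0]\nT [1 0]\n", "column 1 sums to zero"),
        ],
    )
    def test_malformed_records_rejected(self, text, match):
        with pytest.raises(MotifParseError, match=match):
            parse_jaspar(text)


# --- PFM -> PWM ---------------------------------------------------------------


class TestPfmToPwm:
    def test_hand_arithmetic_single_column(self, toy_pwm):
        # counts A:4, pseudocount 0.8 uniform: f_A = 4.2/4.8, w = log2(3.5)
        assert toy_pwm.weights[0, 0] == pytest.approx(math.log2(3.5), abs=1e-12)
        assert toy_pwm.weights[1, 0] == pytest.approx(
            math.log2(0.2 / 4.8 / 0.25), abs=1e-12
        )

    def test_uniform_column_uniform_background_zero_weights(self):
        # the uniform column contributes exactly zero weights; an entirely
        # uniform matrix is degenerate (s_min == s_max) and is rejected
        pfm = parse_jaspar(">U x\nA [1 9]\nC [1 0]\nG [1 0]\nT [1 0]\n")[0]
        pwm = pfm_to_pwm(pfm, ScoreParams(pseudocount=0.8))
        np.testing.assert_array_equal(pwm.weights[:, 0], np.zeros(4))
        all_uniform = parse_jaspar(">U2 x\nA [1]\nC [1]\nG [1]\nT [1]\n")[0]
        with pytest.raises(DegenerateMatrixError):
            pfm_to_pwm(all_uniform)

    def test_argmax_preserved_under_uniform_background(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            pfm = random_pfm(rng, int(rng.integers(1, 7)))
            pwm = pfm_to_pwm(pfm)
            for j in range(pfm.width):
                col = pfm.counts[:, j]
                assert col[np.argmax(pwm.weights[:, j])] == col.max()

    def test_degenerate_matrix_rejected(self):
        pfm = parse_jaspar(">D x\nA [1 1]\nC [1 1]\nG [1 1]\nT [1 1]\n")[0]
        with pytest.raises(DegenerateMatrixError):
            pfm_to_pwm(pfm)

    def test_extrema_match_exhaustive_enumeration(self):
        # s_min/s_max equal brute-force extremes over all 4^w words (w <= 8)
        rng = np.random.default_rng(5)
        for width in (1, 2, 3, 5, 8):
            pwm = pfm_to_pwm(random_pfm(rng, width))
            scores = [
                oracle_score(pwm, "".join(word))
                for word in itertools.product("ACGT", repeat=width)
            ]
            assert pwm.s_min == pytest.approx(min(scores), abs=1e-12)
            assert pwm.s_max == pytest.approx(max(scores), abs=1e-12)


class TestRelativeScore:
    def test_bounds(self, toy_pwm):
        assert relative_score(toy_pwm, toy_pwm.s_max) == 1.0
        assert relative_score(toy_pwm, toy_pwm.s_min) == 0.0

    def test_against_dinucleotide_enumeration(self, toy_pwm):
        raw = oracle_score(toy_pwm, "AC")
        all_scores = [
            oracle_score(toy_pwm, a + b)
            for a in "ACGT" for b in "ACGT"
        ]
        expected = (raw - min(all_scores)) / (max(all_scores) - min(all_scores))
        assert relative_score(toy_pwm, raw) == pytest.approx(expected, abs=1e-12)
        assert expected == 1.0  # AC is the consensus word

    def test_strictly_increasing(self, ebox_pwm):
        xs = np.linspace(ebox_pwm.s_min, ebox_pwm.s_max, 10)
        rels = [relative_score(ebox_pwm, x) for x in xs]
        assert all(a < b for a, b in zip(rels, rels[1:]))


# --- scanning -----------------------------------------------------------------


class TestScanPwm:
    def test_palindromic_consensus_hit_both_strands(self, ebox_pwm):
        region = region_from_sequence("TTTTCACGTGTT")
        hits = scan_pwm(ebox_pwm, region)
        assert [(h.rel_start, h.strand) for h in hits] == [(-8, "+"), (-8, "-")]
        assert all(h.rel_score == pytest.approx(1.0) for h in hits)
        assert all(h.matched == "CACGTG" for h in hits)

    def test_no_hits_on_all_t(self, ebox_pwm):
        region = region_from_sequence("T" * 40)
        assert scan_pwm(ebox_pwm, region) == []

    def test_windows_with_n_skipped(self, ebox_pwm):
        seq = "TTTTCACGNGTT"
        region = region_from_sequence(seq)
        # at threshold 0 every N-free window passes on both strands
        hits = scan_pwm(ebox_pwm, region, ScanConfig(rel_threshold=0.0))
        n_free = sum("N" not in seq[i : i + 6] for i in range(len(seq) - 5))
        assert len(hits) == 2 * n_free
        assert all("N" not in h.matched for h in hits)

    def test_motif_wider_than_region_rejected(self, ebox_pwm):
        with pytest.raises(ValueError, match="width"):
            scan_pwm(ebox_pwm, region_from_sequence("ACG"))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(303)
        for _ in range(30):
            pwm = pfm_to_pwm(random_pfm(rng, int(rng.integers(1, 6))))
            seq = random_sequence(rng, int(rng.integers(20, 200)), "ACGTN")
            tau = float(rng.uniform(0.5, 1.0))
            region = region_from_sequence(seq)
            hits = scan_pwm(pwm, region, ScanConfig(rel_threshold=tau))
            got = [(h.rel_start, h.strand, h.raw_score, h.rel_score) for h in hits]
            exp = oracle_scan(pwm, seq, tau)
            assert len(got) == len(exp)
            for g, e in zip(got, exp):
                assert g[0] == e[0] and g[1] == e[1]
                assert g[2] == pytest.approx(e[2], abs=1e-9)
                assert g[3] == pytest.approx(e[3], abs=1e-9)

    def test_raising_threshold_never_adds_hits(self, ebox_pwm):
        rng = np.random.default_rng(12)
        seq = random_sequence(rng, 300)
        region = region_from_sequence(seq)
        prev = None
        for tau in (0.3, 0.5, 0.7, 0.85, 0.95, 1.0):
            keys = {
                (h.rel_start, h.strand)
                for h in scan_pwm(ebox_pwm, region, ScanConfig(rel_threshold=tau))
            }
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(21)
        pwm = pfm_to_pwm(random_pfm(rng, 4))
        seq = random_sequence(rng, 120)
        fwd = scan_pwm(pwm, region_from_sequence(seq), ScanConfig(rel_threshold=0.8))
        rev = scan_pwm(
            pwm,
            region_from_sequence(reverse_complement(seq)),
            ScanConfig(rel_threshold=0.8),
        )
        assert len(fwd) == len(rev)
        L, w = len(seq), pwm.width
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (-L - h.rel_start - w, flip[h.strand]) for h in fwd
        )
        assert mirrored == sorted((h.rel_start, h.strand) for h in rev)

    def test_translation_invariance(self, ebox_pwm):
        rng = np.random.default_rng(31)
        seq = random_sequence(rng, 150)
        k = 37
        base = scan_pwm(ebox_pwm, region_from_sequence(seq),
                        ScanConfig(rel_threshold=0.6))
        shifted = scan_pwm(
            ebox_pwm,
            region_from_sequence(random_sequence(rng, k)[: k - 6] + "T" * 6 + seq),
            ScanConfig(rel_threshold=0.6),
        )
        base_keys = {(h.rel_start, h.strand) for h in base}
        # every original hit reappears shifted k further upstream... i.e. the
        # original positions are preserved because rel is anchored at the TSS
        shifted_keys = {(h.rel_start, h.strand) for h in shifted}
        assert base_keys <= shifted_keys
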