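"""PWM construction, relative scoring, scanning and probe diffing.

The scanner is checked against a naive oracle that scores every window
independently with a per-position Python loop, and against Bio.motifs'
PSSM as a second, externally maintained implementation of the same
log-odds arithmetic.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmscan import (
    PFM,
    MotifHit,
    ScanConfig,
    diff_blocks,
    pfm_to_pwm,
    relative_score,
    scan_sequence,
)
from crmscan.genome_io import reverse_complement
from crmscan.motifs import BASES, raw_score

from conftest import random_pfm, random_sequence


def naive_raw_score(pwm, word):
    return sum(pwm.weights[j][BASES.index(b)] for j, b in enumerate(word))


def naive_scan(seq, pwm, threshold, both_strands):
    """Score every window independently; the scanning oracle."""
    L = len(pwm)
    denom = pwm.max_score - pwm.min_score
    out = []
    for i in range(len(seq) - L + 1):
        word = seq[i : i + L]
        if set(word) - set("ACGT"):
            continue
        for strand, w in (("+", word), ("-", reverse_complement(word))):
            if strand == "-" and not both_strands:
                continue
            rel = (naive_raw_score(pwm, w) - pwm.min_score) / denom
            if rel >= threshold - 1e-12:
                out.append((i, strand, round(rel, 9)))
    return sorted(out)


class TestPfmToPwm:
    def test_uniform_column_gives_zero_weights(self):
        pfm = PFM(np.ones((3, 4)))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        assert np.allclose(pwm.weights, 0.0)

    def test_hand_evaluated_column(self):
        # column A:10 C:0 G:0 T:0, total pseudocount 1 spread uniformly
        pfm = PFM(np.array([[10, 0, 0, 0], [10, 0, 0, 0]], dtype=float))
        pwm = pfm_to_pwm(pfm, pseudocount=1.0)
        assert pwm.weights[0, 0] == pytest.approx(math.log2((10.25 / 11) / 0.25))
        assert pwm.weights[0, 1] == pytest.approx(math.log2((0.25 / 11) / 0.25))

    def test_count_scaling_invariance_in_small_pseudocount_limit(self):
        counts = np.array([[8, 2, 1, 4], [1, 1, 9, 2]], dtype=float)
        a = pfm_to_pwm(PFM(counts), pseudocount=1e-9)
        b = pfm_to_pwm(PFM(counts * 10), pseudocount=1e-9)
        assert np.allclose(a.weights, b.weights, atol=1e-6)

    def test_zero_counts_require_pseudocount(self):
        pfm = PFM(np.array([[10, 0, 0, 0]], dtype=float))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, pseudocount=0.0)

    def test_matches_biopython_pssm(self, sharp_pfm):
        """Cross-check against Bio.motifs' independently maintained log-odds."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        pwm = pfm_to_pwm(sharp_pfm, pseudocount=1.0)
        m = bio_motifs.Motif(
            counts={b: sharp_pfm.counts[:, i].tolist() for i, b in enumerate("ACGT")}
        )
        # total pseudocount 1 spread by the uniform background = 0.25 per cell
        pssm = m.counts.normalize(pseudocounts=0.25).log_odds(
            {b: 0.25 for b in "ACGT"}
        )
        theirs = np.column_stack([pssm[b] for b in "ACGT"])
        assert np.allclose(pwm.weights, theirs, atol=1e-9)
        assert pwm.max_score == pytest.approx(pssm.max)
        assert pwm.min_score == pytest.approx(pssm.min)


class TestRelativeScore:
    def test_consensus_and_anticonsensus_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            pwm = pfm_to_pwm(random_pfm(rng))
            assert relative_score(pwm, pwm.consensus()) == pytest.approx(1.0)
            assert relative_score(pwm, pwm.anti_consensus()) == pytest.approx(0.0)

    def test_all_dinucleotides_against_manual_summation(self, two_col_pfm):
        """Brute-force enumeration of all 16 words on the 2-column matrix."""
        pwm = pfm_to_pwm(two_col_pfm, pseudocount=1.0)
        denom = pwm.max_score - pwm.min_score
        for word in map("".join, itertools.product("ACGT", repeat=2)):
            expected = (naive_raw_score(pwm, word) - pwm.min_score) / denom
            assert relative_score(pwm, word) == pytest.approx(expected)

    def test_word_with_n_is_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            relative_score(sharp_pwm, "TTNATGGA")

    def test_wrong_length_rejected(self, sharp_pwm):
        with pytest.raises(ValueError):
            relative_score(sharp_pwm, "TTT")


class TestScanSequence:
    def test_sequence_shorter_than_motif_gives_no_hits(self, sharp_pwm):
        assert scan_sequence("ACG", sharp_pwm) == []

    def test_planted_consensus_found_with_offset(self, sharp_pwm):
        rng = np.random.default_rng(3)
        background = random_sequence(rng, 60)
        seq = background[:20] + sharp_pwm.consensus() + background[20:]
        hits = scan_sequence(seq, sharp_pwm, ScanConfig(), chrom="c", offset=1000)
        plus = [h for h in hits if h.strand == "+" and h.relative_score == 1.0]
        assert any(h.interval.start == 1020 for h in plus)

    def test_windows_containing_n_are_skipped(self, sharp_pwm):
        seq = sharp_pwm.consensus()[:-1] + "N"
        assert scan_sequence(seq, sharp_pwm, ScanConfig(relative_threshold=0.01)) == []

    def test_agrees_with_naive_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pfm = random_pfm(rng)
            pwm = pfm_to_pwm(pfm)
            seq = random_sequence(rng, int(rng.integers(0, 200)), "ACGTN")
            threshold = float(rng.uniform(0.5, 1.0))
            cfg = ScanConfig(relative_threshold=threshold, both_strands=True)
            got = sorted(
                (h.interval.start, h.strand, round(h.relative_score, 9))
                for h in scan_sequence(seq, pwm, cfg)
            )
            assert got == naive_scan(seq, pwm, threshold, True)

    def test_hit_count_nonincreasing_in_threshold(self, sharp_pwm):
        rng = np.random.default_rng(5)
        seq = random_sequence(rng, 2000)
        counts = [
            len(scan_sequence(seq, sharp_pwm, ScanConfig(relative_threshold=t)))
            for t in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry(self, sharp_pwm):
        """Both-strand scan of seq = forward scans of seq and its reverse
        complement, as a multiset of relative scores; coordinates mirror."""
        rng = np.random.default_rng(8)
        seq = random_sequence(rng, 300)
        cfg_both = ScanConfig(relative_threshold=0.7, both_strands=True)
        cfg_fwd = ScanConfig(relative_threshold=0.7, both_strands=False)
        both = scan_sequence(seq, sharp_pwm, cfg_both)
        fwd = scan_sequence(seq, sharp_pwm, cfg_fwd)
        rc = scan_sequence(reverse_complement(seq), sharp_pwm, cfg_fwd)
        assert sorted(round(h.relative_score, 9) for h in both) == sorted(
            round(h.relative_score, 9) for h in fwd + rc
        )
        # mirror image: (start, -) on seq <-> (len - end, +) on revcomp(seq)
        minus = {h.interval.start for h in both if h.strand == "-"}
        mirrored = {len(seq) - h.interval.end for h in rc}
        assert minus == mirrored

    def test_matches_biopython_pssm_search(self, sharp_pfm):
        """Raw window scores agree with Bio.motifs PSSM.calculate."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        rng = np.random.default_rng(23)
        seq = random_sequence(rng, 500)
        pwm = pfm_to_pwm(sharp_pfm)
        m = bio_motifs.Motif(
            counts={b: sharp_pfm.counts[:, i].tolist() for i, b in enumerate("ACGT")}
        )
        pssm = m.counts.normalize(pseudocounts=0.25).log_odds({b: 0.25 for b in "ACGT"})
        theirs = pssm.calculate(Seq(seq))
        hits = scan_sequence(seq, pwm, ScanConfig(relative_threshold=0.01, both_strands=False))
        for h in hits:
            assert h.raw_score == pytest.approx(float(theirs[h.interval.start]), abs=1e-4)


class TestDiffBlocks:
    def test_identical_strings(self):
        assert diff_blocks("ACGT", "ACGT") == []

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            diff_blocks("ACG", "AC")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_positionwise_grouping(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        a = random_sequence(rng, n)
        b = "".join(
            c if rng.random() < 0.7 else rng.choice(list("ACGT")) for c in a
        )
        blocks = diff_blocks(a, b)
        mism = [i for i in range(n) if a[i] != b[i]]
        rebuilt = [i for s, ln in blocks for i in range(s, s + ln)]
        assert rebuilt == mism
        # blocks are maximal: no two adjacent blocks touch
        for (s1, l1), (s2, _) in zip(blocks, blocks[1:]):
            assert s1 + l1 < s2
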