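import itertools

import numpy as np
import pytest

from irkit.motifs import (
    PWM,
    extract_flanks,
    pwm_score,
    read_pwms,
    region_enrichment,
    reverse_complement,
    scan_region,
    score_distribution,
    score_threshold,
    write_pwms_tab,
)
from irkit.reference import IntronRecord


def consensus_pwm(consensus, p=0.97, pseudocount=0.0):
    rows = []
    for ch in consensus:
        row = [(1 - p) / 3] * 4
        row["ACGT".index(ch)] = p
        rows.append(row)
    return PWM("m1", "RBP1", np.array(rows), pseudocount=pseudocount)


MEME_MINIMAL = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF m1
letter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0
0.970000 0.010000 0.010000 0.010000
0.010000 0.970000 0.010000 0.010000
0.010000 0.010000 0.970000 0.010000
"""


class TestPwmIO:
    def test_meme_minimal_single_motif(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_MINIMAL)
        (pwm,) = read_pwms(str(p), format="meme")
        assert pwm.length == 3
        assert pwm.consensus == "ACG"
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_pseudocount_regularizes_zero_rows(self):
        pwm = PWM("z", "z", np.array([[0.5, 0.5, 0.0, 0.0]]), pseudocount=1e-3)
        assert (pwm.matrix > 0).all()
        assert pwm.matrix.sum() == pytest.approx(1.0)

    def test_tab_round_trip(self, tmp_path):
        pwms = [consensus_pwm("ACGT"), consensus_pwm("TTG")]
        p = tmp_path / "x.tab"
        write_pwms_tab(pwms, str(p))
        back = read_pwms(str(p), format="attract-tab")
        for a, b in zip(pwms, back):
            assert b.motif_id == a.motif_id and b.rbp_name == a.rbp_name
            # reader re-applies its own pseudocount; compare pre-regularized rows
            np.testing.assert_allclose(b.matrix, (a.matrix + b.pseudocount) / (1 + 4 * b.pseudocount), atol=1e-9)

    def test_unnormalized_row_renormalized_with_warning(self, tmp_path):
        p = tmp_path / "bad.tab"
        p.write_text(">m\trbp\n0.5\t0.5\t0.5\t0.5\n")
        with pytest.warns(UserWarning, match="renormaliz"):
            (pwm,) = read_pwms(str(p), format="attract-tab")
        assert pwm.matrix.sum() == pytest.approx(1.0)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.tab"
        p.write_text("")
        with pytest.raises(ValueError):
            read_pwms(str(p), format="attract-tab")


class TestPwmScore:
    def test_certain_base_scores_two_bits(self):
        pwm = PWM("a", "a", np.array([[1.0, 0, 0, 0]]), pseudocount=0.0)
        assert pwm_score("A", pwm) == pytest.approx(2.0)

    def test_background_window_scores_zero(self):
        pwm = PWM("b", "b", np.array([[0.25] * 4, [0.25] * 4]), pseudocount=0.0)
        assert pwm_score("CT", pwm) == pytest.approx(0.0)

    def test_hand_summed_three_mer(self):
        mat = np.array([[0.5, 0.2, 0.2, 0.1], [0.1, 0.6, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]])
        pwm = PWM("c", "c", mat, pseudocount=0.0)
        expected = np.log2(0.5 / 0.25) + np.log2(0.2 / 0.25) + np.log2(0.25 / 0.25)
        assert pwm_score("AG" + "T", pwm) == pytest.approx(expected)

    def test_n_contributes_zero(self):
        pwm = consensus_pwm("AC", pseudocount=0.0)
        assert pwm_score("NC", pwm) == pytest.approx(pwm_score("AC", pwm) - pwm_score("A", consensus_pwm("A", pseudocount=0.0)))

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            pwm_score("AX", consensus_pwm("AA"))


def brute_force_distribution(pwm, bin_width=0.01):
    """Enumerate all 4^L windows under the background model.

    Per-position scores are floored to bins exactly as the DP discretizes, so
    the two distributions must agree identically (the "up to binning"
    equivalence).
    """
    kmat = np.floor(pwm.log_odds / bin_width).astype(int)
    probs = {}
    for window in itertools.product(range(4), repeat=pwm.length):
        k = int(sum(kmat[i, b] for i, b in enumerate(window)))
        p = np.prod([pwm.background[b] for b in window])
        probs[k] = probs.get(k, 0.0) + p
    return probs


class TestScoreThreshold:
    def test_single_position_quarter_target(self):
        pwm = consensus_pwm("A", pseudocount=0.0)
        thr = score_threshold(pwm, p_target=0.25)
        s_a = pwm_score("A", pwm)
        assert thr <= s_a < thr + 0.01 + 1e-9  # lower bin edge of A's score
        assert scan_region("A", pwm, thr) == 1

    def test_p_target_one_gives_minimum(self):
        pwm = consensus_pwm("ACG", pseudocount=0.0)
        thr = score_threshold(pwm, p_target=1.0)
        worst = min(pwm_score("".join(w), pwm)
                    for w in itertools.product("ACGT", repeat=3))
        assert thr <= worst

    @pytest.mark.parametrize("consensus", ["ACG", "TTGCA"])
    def test_dp_matches_enumeration(self, consensus):
        pwm = consensus_pwm(consensus, pseudocount=0.0)
        offsets, probs = score_distribution(pwm, bin_width=0.01)
        brute = brute_force_distribution(pwm, bin_width=0.01)
        dp = {int(k): p for k, p in zip(offsets, probs) if p > 0}
        all_keys = set(dp) | set(brute)
        tv = 0.5 * sum(abs(dp.get(k, 0.0) - brute.get(k, 0.0)) for k in all_keys)
        assert tv <= 1e-9

    def test_total_mass_is_one(self):
        pwm = consensus_pwm("ACGTTG", pseudocount=0.0)
        _, probs = score_distribution(pwm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_p_target(self):
        pwm = consensus_pwm("ACGT", pseudocount=0.0)
        thrs = [score_threshold(pwm, p) for p in (1e-4, 1e-3, 1e-2, 0.5)]
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))


class TestScanRegion:
    def test_planted_consensus_counted(self):
        pwm = consensus_pwm("ACGTA", pseudocount=0.0)
        thr = pwm_score("ACGTA", pwm)
        seq = "TT" + "ACGTA" + "GGGG" + "ACGTA" + "C"
        assert scan_region(seq, pwm, thr) == 2

    def test_threshold_above_max_gives_zero(self):
        pwm = consensus_pwm("ACGTA", pseudocount=0.0)
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        assert scan_region(seq, pwm, pwm_score("ACGTA", pwm) + 1) == 0

    def test_short_sequence_zero(self):
        pwm = consensus_pwm("ACGTA")
        assert scan_region("ACG", pwm, -100) == 0

    def test_matches_exhaustive_scan_on_random_kb(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        pwm = consensus_pwm("TGCAT", pseudocount=0.0)
        thr = score_threshold(pwm, p_target=1e-3)
        expected = sum(
            pwm_score(seq[i : i + pwm.length], pwm) >= thr
            for i in range(len(seq) - pwm.length + 1)
        )
        assert scan_region(seq, pwm, thr) == expected

    def test_prefix_shift_equivariance(self):
        rng = np.random.default_rng(6)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        prefix = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        pwm = consensus_pwm("ACGT", pseudocount=0.0)
        thr = score_threshold(pwm, p_target=1e-2)
        joined = prefix + seq
        # hits in the joined sequence = hits of the prefix region (windows
        # starting inside prefix) + hits of seq
        prefix_hits = sum(
            pwm_score(joined[i : i + 4], pwm) >= thr for i in range(len(prefix))
        )
        assert scan_region(joined, pwm, thr) == prefix_hits + scan_region(seq, pwm, thr)


def toy_intron(strand="+"):
    return IntronRecord(
        intron_id=f"chr1:100-200:{strand}:g1", gene_id="g1", chrom="chr1",
        strand=strand, start=100, end=200, left_exon=(0, 100), right_exon=(200, 300),
    )


class TestExtractFlanks:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        self.genome = {"chr1": self.seq}

    def test_plus_strand_literal_substrings(self):
        regions = {r.region_tag: r for r in extract_flanks(self.genome, [toy_intron("+")])}
        assert regions["5p_exon"].sequence == self.seq[50:100]
        assert regions["5p_intron"].sequence == self.seq[100:150]
        assert regions["3p_intron"].sequence == self.seq[150:200]
        assert regions["3p_exon"].sequence == self.seq[200:250]
        assert not any(r.truncated for r in regions.values())

    def test_minus_strand_mirrored_revcomp(self):
        regions = {r.region_tag: r for r in extract_flanks(self.genome, [toy_intron("-")])}
        assert regions["5p_exon"].sequence == reverse_complement(self.seq[200:250])
        assert regions["5p_intron"].sequence == reverse_complement(self.seq[150:200])
        assert regions["3p_intron"].sequence == reverse_complement(self.seq[100:150])
        assert regions["3p_exon"].sequence == reverse_complement(self.seq[50:100])

    def test_short_exon_truncated_and_flagged(self):
        rec = IntronRecord("chr1:100-200:+:g1", "g1", "chr1", "+", 100, 200,
                           left_exon=(70, 100), right_exon=(200, 300))
        regions = {r.region_tag: r for r in extract_flanks(self.genome, [rec])}
        assert len(regions["5p_exon"].sequence) == 30
        assert regions["5p_exon"].truncated

    def test_reverse_complement_scan_consistency(self):
        # scanning a minus-strand transcript flank equals scanning the
        # reverse complement of its genomic window
        pwm = consensus_pwm("TGCAT", pseudocount=0.0)
        thr = score_threshold(pwm, p_target=1e-2)
        regions = {r.region_tag: r for r in extract_flanks(self.genome, [toy_intron("-")])}
        genomic_window = self.genome["chr1"][150:200]
        assert scan_region(regions["5p_intron"], pwm, thr) == scan_region(
            reverse_complement(genomic_window), pwm, thr
        )


class TestRegionEnrichment:
    def test_identical_groups(self):
        res = region_enrichment([1, 2, 3], [1, 2, 3])
        assert res.t_stat == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_constant_groups_hand_computed(self):
        res = region_enrichment([2, 2, 2, 2], [0, 0, 0, 0])
        assert res.mean_freq_ir - res.mean_freq_nr == pytest.approx(2.0)
        assert res.degenerate and res.p == 0.0 and res.t_stat > 0

    def test_hand_pooled_t(self):
        a, b = [3, 1, 2, 2], [0, 1, 0, 1]
        res = region_enrichment(a, b)
        am, bm = np.mean(a), np.mean(b)
        sp2 = (np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6
        t_hand = (am - bm) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert res.t_stat == pytest.approx(t_hand)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            region_enrichment([1], [1, 2])
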