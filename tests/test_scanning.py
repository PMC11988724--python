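"""PWM construction, exact p-value calibration, and strand-aware scanning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promotif import (PFM, build_log_odds, gen_pwm, parse_jaspar_pfm,
                      reverse_complement, scan_sequence, score_distribution,
                      score_threshold_for_pvalue)

JASPAR_OK = """>MA0001.1 test
A [ 3 10  2  5  1  0 ]
C [ 2  0  8  1  1  2 ]
G [ 4  0  0  3  7  8 ]
T [ 1  0  0  1  1  0 ]
"""

JASPAR_SHUFFLED = """>MA0002.1 shuffled
T [ 1 2 ]
G [ 3 4 ]
C [ 5 6 ]
A [ 7 8 ]
"""


class TestParseJaspar:
    def test_well_formed(self):
        pfm = parse_jaspar_pfm(JASPAR_OK)
        assert pfm.length == 6
        assert pfm.motif_id == "MA0001.1"
        assert pfm.counts[0, 1] == 10

    def test_rows_reordered_by_label(self):
        pfm = parse_jaspar_pfm(JASPAR_SHUFFLED)
        assert pfm.counts[:, 0].tolist() == [7, 5, 3, 1]  # A,C,G,T order

    @pytest.mark.parametrize("bad", [
        ">x\nA [1 2]\nC [1 2]\nG [1 2]\n",          # missing T row
        ">x\nA [1 2]\nC [1 2]\nG [1 2]\nT [1]\n",    # ragged
        ">x\nA [1 -2]\nC [1 2]\nG [1 2]\nT [1 2]\n",  # negative
    ])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_jaspar_pfm(bad)


class TestLogOdds:
    def test_uniform_column_near_zero(self):
        pfm = PFM(counts=np.full((4, 3), 25))
        pwm = build_log_odds(pfm, pseudocount=1e-9)
        assert np.allclose(pwm.log_odds, 0.0, atol=1e-9)

    def test_single_base_column_sign_pattern(self):
        counts = np.zeros((4, 1), int)
        counts[2, 0] = 40
        pwm = build_log_odds(PFM(counts=counts), pseudocount=1.0)
        assert pwm.log_odds[2, 0] > 0
        assert all(pwm.log_odds[b, 0] < 0 for b in (0, 1, 3))

    def test_consensus_score_is_columnwise_max_sum(self):
        pwm = build_log_odds(parse_jaspar_pfm(JASPAR_OK))
        assert pwm.score_word(pwm.consensus) == pytest.approx(
            pwm.log_odds.max(axis=0).sum())

    def test_bad_args(self):
        pfm = parse_jaspar_pfm(JASPAR_OK)
        with pytest.raises(ValueError):
            build_log_odds(pfm, pseudocount=0.0)


class TestThreshold:
    def test_alpha_one_gives_minimum_score(self, sharp_pwm):
        thr, tail, dist = score_threshold_for_pvalue(sharp_pwm, alpha=1.0)
        assert thr == pytest.approx(dist.scores[0])
        assert tail == pytest.approx(1.0)

    def test_unique_consensus_trinucleotide(self):
        pwm = build_log_odds(gen_pwm(4, seed=2, sharpness=1.0))
        # degenerate matrix: only the consensus attains the maximum score
        thr, tail, _ = score_threshold_for_pvalue(pwm, alpha=0.005)
        assert thr == pytest.approx(pwm.max_score, abs=0.02)
        assert tail == pytest.approx(0.25 ** 4)

    @pytest.mark.parametrize("L,seed", [(4, 0), (5, 1), (8, 2)])
    def test_convolution_matches_enumeration(self, L, seed):
        """DP tail probabilities equal exhaustive 4^L word enumeration."""
        pwm = build_log_odds(gen_pwm(L, seed=seed, sharpness=0.5))
        dist = score_distribution(pwm, bin_width=0.01)
        cols = np.rint(pwm.log_odds / 0.01).astype(int)
        pmf: dict[int, float] = {}
        for word in itertools.product(range(4), repeat=L):
            s = int(sum(cols[b, j] for j, b in enumerate(word)))
            pmf[s] = pmf.get(s, 0.0) + 0.25 ** L
        grid = np.rint(dist.scores / 0.01).astype(int)
        assert set(grid) == set(pmf)
        for g, p in zip(grid, dist.pmf):
            assert p == pytest.approx(pmf[int(g)], abs=1e-12)

    def test_invalid(self, sharp_pwm):
        with pytest.raises(ValueError):
            score_threshold_for_pvalue(sharp_pwm, alpha=0.0)
        with pytest.raises(ValueError):
            score_distribution(sharp_pwm, bin_width=-1)


class TestScan:
    def _background(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_planted_consensus_plus_strand(self, sharp_pwm):
        cons = sharp_pwm.consensus
        seq = list(self._background(1000, seed=3))
        seq[100:106] = cons  # index 100 -> position -900
        # a degenerate PWM only reaches max_score at the consensus itself
        hits = scan_sequence(sharp_pwm, "".join(seq),
                             threshold=sharp_pwm.max_score - 1e-6)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.position for h in plus] == [-900]
        assert plus[0].matched_seq == cons

    def test_reverse_complement_plant_maps_back(self, sharp_pwm):
        cons = sharp_pwm.consensus
        seq = list(self._background(1000, seed=4))
        seq[880:886] = reverse_complement(cons)  # 5'-most base at -120
        hits = scan_sequence(sharp_pwm, "".join(seq),
                             threshold=sharp_pwm.max_score - 1e-6)
        minus = [h for h in hits if h.strand == "-"]
        assert [h.position for h in minus] == [-120]

    def test_matches_naive_window_rescoring(self):
        pwm = build_log_odds(gen_pwm(5, seed=5, sharpness=0.4))
        seq = self._background(300, seed=6)
        thr, _, _ = score_threshold_for_pvalue(pwm, alpha=0.05)
        hits = scan_sequence(pwm, seq, thr)
        naive = 0
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - pwm.length + 1):
                w = pwm.score_word(s[i:i + pwm.length])
                if round(w / 0.01) >= round(thr / 0.01):
                    naive += 1
        assert len(hits) == naive

    def test_n_windows_skipped(self, sharp_pwm):
        seq = "N" * 20 + self._background(80, seed=7)
        hits = scan_sequence(sharp_pwm, seq, threshold=-100.0)
        assert all("N" not in h.matched_seq for h in hits)
        # both strands, N-free windows only
        assert len(hits) == 2 * (80 - 6 + 1)

    def test_short_promoter_warns_empty(self, sharp_pwm):
        with pytest.warns(UserWarning):
            assert scan_sequence(sharp_pwm, "ACG", threshold=0.0) == []

    def test_threshold_monotonicity(self, sharp_pwm):
        seq = self._background(500, seed=8)
        counts = [len(scan_sequence(sharp_pwm, seq, t))
                  for t in np.linspace(sharp_pwm.min_score,
                                       sharp_pwm.max_score, 9)]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=60))
    def test_strand_symmetry(self, seq):
        pwm = build_log_odds(gen_pwm(4, seed=9, sharpness=0.6))
        fwd = scan_sequence(pwm, seq, threshold=2.0)
        rev = scan_sequence(pwm, reverse_complement(seq), threshold=2.0)
        n = len(seq)

        def key(h, flip):
            strand = {"+": "-", "-": "+"}[h.strand] if flip else h.strand
            pos = -(h.position + n) - pwm.length if flip else h.position
            return (pos, strand, round(h.score, 9))

        assert sorted(key(h, False) for h in fwd) == \
            sorted(key(h, True) for h in rev)

    def test_calibration_of_exceedance_rate(self):
        """Mean per-window hit rate at the p=0.01 threshold matches the
        returned tail probability within binomial error."""
        pwm = build_log_odds(gen_pwm(6, seed=10, sharpness=0.5))
        thr, tail, dist = score_threshold_for_pvalue(pwm, alpha=0.01)
        rng = np.random.default_rng(11)
        exceed = total = 0
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            hits = scan_sequence(pwm, seq, thr, distribution=dist)
            exceed += sum(1 for h in hits if h.strand == "+")
            total += 500 - 6 + 1
        rate = exceed / total
        se = np.sqrt(tail * (1 - tail) / total)
        assert abs(rate - tail) < 4 * se
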