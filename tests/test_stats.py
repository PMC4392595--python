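"""Region-set statistics: permutation, hypergeometric, chi-squared,
signed-rank exactness, and PWM motif enrichment."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from chromdyn.errors import (
    DegenerateInputError,
    InvalidParameterError,
    ValidationError,
)
from chromdyn.genome import Genome
from chromdyn.intervals import GenomicInterval, IntervalSet
from chromdyn.simulate import plant_motif, random_sequences
from chromdyn.stats import (
    PWM,
    chisq_independence,
    hypergeometric_enrichment,
    motif_enrichment,
    paired_rank_test,
    permutation_overlap_test,
    pwm_from_consensus,
    read_jaspar_pwms,
)

GENOME = Genome(("chr1",), (1_000_000,))


def iv(s, e):
    return GenomicInterval("chr1", s, e)


class TestPermutationTest:
    def test_total_overlap_in_sparse_genome_gives_minimal_p(self):
        ref = IntervalSet([iv(i * 100_000, i * 100_000 + 1000) for i in range(5)])
        res = permutation_overlap_test(ref, ref, GENOME, n_perm=500, seed=1)
        assert res.observed == 1.0
        assert res.p == pytest.approx(1 / 501)

    def test_add_one_rule_with_single_permutation(self):
        # reference covers everything: every shuffle ties the observation
        ref = IntervalSet([iv(0, 1_000_000)])
        q = IntervalSet([iv(0, 100)])
        res = permutation_overlap_test(q, ref, GENOME, n_perm=1, seed=0)
        assert res.p == 1.0

    def test_deterministic_given_seed(self):
        ref = IntervalSet([iv(50_000, 60_000)])
        q = IntervalSet([iv(i * 9000, i * 9000 + 500) for i in range(20)])
        a = permutation_overlap_test(q, ref, GENOME, n_perm=200, seed=9)
        b = permutation_overlap_test(q, ref, GENOME, n_perm=200, seed=9)
        assert a.p == b.p and np.array_equal(a.null, b.null)

    def test_pvalues_uniform_under_null(self):
        """200 independent datasets with no planted relationship produce
        approximately uniform permutation p-values."""
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            # enough query intervals that the overlap-fraction statistic is
            # fine-grained; coarse lattices leave the add-one p conservative
            q = IntervalSet(
                [iv(int(s), int(s) + 500) for s in rng.integers(0, 999_000, 150)]
            )
            ref = IntervalSet(
                [iv(int(s), int(s) + 2000) for s in rng.integers(0, 990_000, 60)]
            )
            res = permutation_overlap_test(
                q, ref, GENOME, n_perm=99, seed=int(rng.integers(2**31))
            )
            pvals.append(res.p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_slow_path_with_exclusions_matches_invariants(self):
        q = IntervalSet([iv(1000, 1500), iv(5000, 5600)])
        ref = IntervalSet([iv(100_000, 200_000)])
        excl = IntervalSet([iv(0, 900_000)])
        res = permutation_overlap_test(q, ref, GENOME, excluded=excl,
                                       n_perm=50, seed=2)
        assert 0 < res.p <= 1
        assert len(res.null) == 50


class TestHypergeometric:
    def test_all_hits_in_small_universe(self):
        p = hypergeometric_enrichment(5, 5, 5, 10)
        assert p == pytest.approx(1 / math.comb(10, 5), rel=1e-12)

    def test_zero_hits_gives_one(self):
        assert hypergeometric_enrichment(0, 4, 3, 10) == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        """Exact combinatorial oracle over a lattice of configurations."""
        for N in range(1, 31, 3):
            for K in range(0, N + 1, 2):
                for s in range(0, N + 1, 2):
                    for k in range(max(0, K + s - N), min(K, s) + 1):
                        oracle = sum(
                            math.comb(K, j) * math.comb(N - K, s - j)
                            for j in range(k, min(K, s) + 1)
                        ) / math.comb(N, s)
                        got = hypergeometric_enrichment(k, s, K, N)
                        assert got == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(6, 5, 6, 10)


class TestChiSquared:
    def test_independent_table(self):
        chi2, df, p = chisq_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_hand_computed_table(self):
        # Pearson by hand: every expected cell is 12.5, so
        # chi2 = 4 * (7.5)^2 / 12.5 = 18; equivalently N*(ad-bc)^2/(r1*r2*c1*c2)
        chi2, _, p = chisq_independence([[20, 5], [5, 20]])
        assert chi2 == pytest.approx(50 * (20 * 20 - 5 * 5) ** 2 / 25**4)
        assert chi2 == pytest.approx(18.0)
        assert p == pytest.approx(sps.chi2.sf(18.0, 1), rel=1e-12)

    def test_homogeneity_scaling(self):
        chi2a, _, _ = chisq_independence([[20, 5], [5, 20]])
        chi2b, _, _ = chisq_independence([[40, 10], [10, 40]])
        assert chi2b == pytest.approx(2 * chi2a)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            chisq_independence([[0, 0], [5, 20]])

    def test_yates_option_reduces_statistic(self):
        plain, _, _ = chisq_independence([[20, 5], [5, 20]])
        corrected, _, _ = chisq_independence([[20, 5], [5, 20]], yates=True)
        assert corrected < plain


class TestPairedRank:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_rank_test([1.0, 2.0], [1.0, 2.0])

    def test_five_positive_differences(self):
        w, p = paired_rank_test([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    @staticmethod
    def _brute_force_p(diffs):
        d = np.asarray(diffs, float)
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        mean = ranks.sum() / 2
        count_ge = count_le = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count_ge += w >= w_obs
            count_le += w <= w_obs
        total = 2**n
        return min(1.0, 2 * min(count_ge / total, count_le / total))

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_mode_matches_sign_flip_enumeration(self, n, rng):
        for _ in range(5):
            ctrl = rng.normal(0, 1, n)
            ko = ctrl + rng.normal(0.3, 1, n)
            _, p = paired_rank_test(ctrl, ko)
            assert p == pytest.approx(self._brute_force_p(ko - ctrl), rel=1e-12)

    def test_exact_mode_handles_ties(self, rng):
        ctrl = np.zeros(8)
        ko = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 2.0, -2.0, 3.0])
        _, p = paired_rank_test(ctrl, ko)
        assert p == pytest.approx(self._brute_force_p(ko), rel=1e-12)

    def test_large_n_approximation_close_to_scipy(self, rng):
        ctrl = rng.normal(0, 1, 60)
        ko = ctrl + rng.normal(0.4, 1, 60)
        _, p = paired_rank_test(ctrl, ko)
        ref = sps.wilcoxon(ko - ctrl, correction=False, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_exact_mode_agrees_with_scipy_exact_no_ties(self, rng):
        ctrl = rng.normal(0, 1, 14)
        ko = ctrl + rng.normal(0.5, 1, 14)
        _, p = paired_rank_test(ctrl, ko)
        ref = sps.wilcoxon(ko - ctrl, mode="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestMotifEnrichment:
    MOTIF = "TGACGTCA"

    def _sets(self, rate_bound=0.5, rate_bg=0.1, n=200, seed=0):
        bound = random_sequences(n, 300, seed=seed)
        bg = random_sequences(n, 300, seed=seed + 1)
        bound = plant_motif(bound, self.MOTIF, rate_bound, seed=seed + 2)
        bg = plant_motif(bg, self.MOTIF, rate_bg, seed=seed + 3)
        return bound, bg

    def test_planted_motif_detected(self):
        bound, bg = self._sets()
        pwm = pwm_from_consensus("planted", self.MOTIF)
        df = motif_enrichment([pwm], bound, bg)
        row = df.loc["planted"]
        assert row["fold"] == pytest.approx(5.0, rel=0.5)
        assert row["q_bh"] < 0.001

    def test_identical_sets_fold_one(self):
        bound, _ = self._sets()
        pwm = pwm_from_consensus("planted", self.MOTIF)
        df = motif_enrichment([pwm], bound, bound)
        row = df.loc["planted"]
        assert row["fold"] == pytest.approx(1.0)
        assert row["p"] > 0.3

    def test_reverse_complement_detected_equally(self):
        rc = "TGACGTCA".translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seqs = random_sequences(150, 200, seed=5)
        fwd = plant_motif(seqs, self.MOTIF, 1.0, seed=6)
        pwm = pwm_from_consensus("m", self.MOTIF)
        pwm_rc = pwm_from_consensus("m_rc", rc)
        df = motif_enrichment([pwm, pwm_rc], fwd, random_sequences(150, 200, seed=7))
        assert df.loc["m", "hits_bound"] == df.loc["m_rc", "hits_bound"]

    def test_short_regions_skipped(self):
        pwm = pwm_from_consensus("m", self.MOTIF)
        df = motif_enrichment([pwm], ["ACGT"], ["ACGTACGTACGT"])
        assert df.loc["m", "skipped"] == 1

    def test_fisher_matches_hypergeometric_identity(self):
        bound, bg = self._sets(n=80)
        pwm = pwm_from_consensus("m", self.MOTIF)
        df = motif_enrichment([pwm], bound, bg)
        row = df.loc["m"]
        manual = hypergeometric_enrichment(
            int(row["hits_bound"]),
            int(row["n_bound"]),
            int(row["hits_bound"] + row["hits_background"]),
            int(row["n_bound"] + row["n_background"]),
        )
        assert row["p"] == pytest.approx(manual, rel=1e-9)

    def test_pwm_validation(self):
        with pytest.raises(ValidationError):
            PWM("bad", np.ones((6, 4)))  # rows do not sum to 1
        with pytest.raises(ValidationError):
            PWM("short", np.full((3, 4), 0.25))

    def test_jaspar_roundtrip(self, tmp_path):
        text = (
            ">MA0001.1 test\n"
            "A [ 10  0  0 10 ]\n"
            "C [  0 10  0  0 ]\n"
            "G [  0  0 10  0 ]\n"
            "T [  0  0  0  0 ]\n"
        )
        path = tmp_path / "m.jaspar"
        path.write_text(text)
        pwms = read_jaspar_pwms(path)
        assert len(pwms) == 1
        assert len(pwms[0]) == 4
        assert pwms[0].matrix[0].argmax() == 0  # A dominates position 0
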