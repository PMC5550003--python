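"""Dirichlet-marginal column/pair probabilities and dependency evidence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwt.counts import (
    CountProfile,
    PairCountTensor,
    PriorSpec,
    column_log_prob,
    dependency_log_ratio,
    dependency_matrix,
    encode,
    mutual_information,
    pair_log_prob,
    revcomp_codes,
)


class TestPrior:
    def test_dinucleotide_pseudocount_is_quarter_of_mono(self):
        p = PriorSpec(0.8)
        assert p.lambda_di == pytest.approx(0.2)

    @pytest.mark.parametrize("lam", [0.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, lam):
        with pytest.raises(ValueError):
            PriorSpec(lam)


class TestColumnLogProb:
    @pytest.mark.parametrize("counts, expected", [
        ((0, 0, 0, 0), 0.0),                    # empty column: ratios cancel
        ((1, 0, 0, 0), np.log(1 / 4)),          # single letter: uniform
        ((2, 0, 0, 0), np.log(1 / 8)),          # (1/4) * (1+λ)/(1+4λ)
    ])
    def test_worked_examples(self, counts, expected):
        assert column_log_prob(counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            column_log_prob([-1, 0, 0, 0])

    def test_exchangeable_under_letter_relabeling(self, rng):
        for _ in range(20):
            c = rng.gamma(1.0, 5.0, 4)
            perm = rng.permutation(4)
            assert column_log_prob(c) == pytest.approx(
                column_log_prob(c[perm]), rel=1e-12)

    def test_chain_rule_predictive_increment(self, rng):
        """exp(logP(n + e_a) - logP(n)) = (n_a + λ)/(n + 4λ)."""
        lam = 0.5
        for _ in range(100):
            c = rng.gamma(1.0, 5.0, 4)
            a = rng.integers(4)
            inc = c.copy()
            inc[a] += 1
            lhs = column_log_prob(inc) - column_log_prob(c)
            rhs = np.log((c[a] + lam) / (c.sum() + 4 * lam))
            assert lhs == pytest.approx(rhs, rel=1e-10)


class TestPairLogProb:
    def test_empty_table(self):
        assert pair_log_prob(np.zeros((4, 4))) == 0.0

    def test_single_count_uniform_over_16(self):
        t = np.zeros((4, 4))
        t[0, 0] = 1
        assert pair_log_prob(t) == pytest.approx(np.log(1 / 16), abs=1e-12)

    def test_double_count_same_cell(self):
        t = np.zeros((4, 4))
        t[0, 0] = 2
        assert pair_log_prob(t) == pytest.approx(np.log(0.0234375), abs=1e-12)


class TestDependencyRatio:
    def test_single_observation_carries_no_evidence(self):
        pc = PairCountTensor.from_sites(["AG"])
        assert dependency_log_ratio(pc, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_two_coupled_sites(self):
        pc = PairCountTensor.from_sites(["AA", "AA"])
        assert dependency_log_ratio(pc, 0, 1) == pytest.approx(np.log(1.5))

    def test_relabeling_invariance_of_coupled_columns(self):
        r1 = dependency_log_ratio(PairCountTensor.from_sites(["AA", "CC"]), 0, 1)
        r2 = dependency_log_ratio(PairCountTensor.from_sites(["AC", "CA"]), 0, 1)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_symmetric_in_positions(self, rng):
        pc = PairCountTensor.from_sites(
            ["".join("ACGT"[c] for c in rng.integers(0, 4, 5))
             for _ in range(30)])
        for i in range(5):
            for j in range(i + 1, 5):
                assert dependency_log_ratio(pc, i, j) == pytest.approx(
                    dependency_log_ratio(pc, j, i), rel=1e-12)

    def test_diagonal_rejected(self):
        pc = PairCountTensor.from_sites(["AC"])
        with pytest.raises(ValueError):
            dependency_log_ratio(pc, 1, 1)

    def test_whole_site_outer_products_give_zero_evidence(self):
        # n = 0 and n = 1 are the integer cases where independence is exact
        z = PairCountTensor(np.zeros((3, 3, 4, 4)))
        assert dependency_matrix(z) == pytest.approx(np.zeros((3, 3)))
        one = PairCountTensor.from_sites(["ACG"])
        assert dependency_matrix(one) == pytest.approx(np.zeros((3, 3)),
                                                       abs=1e-12)

    def test_independent_product_drives_logR_over_n_to_zero(self):
        """logR/n -> 0 as independent observations accumulate."""
        lam = PriorSpec()
        pa = np.array([0.5, 0.3, 0.1, 0.1])
        pb = np.array([0.25, 0.25, 0.25, 0.25])
        # the independence Bayes factor grows only like log n, so logR/n -> 0
        prev = np.inf
        for n in (10, 100, 10000):
            t = np.zeros((2, 2, 4, 4))
            t[0, 1] = n * np.outer(pa, pb)
            t[1, 0] = t[0, 1].T
            r = abs(dependency_log_ratio(PairCountTensor(t), 0, 1)) / n
            assert r < prev
            prev = r
        assert prev < 0.01


class TestMutualInformation:
    def test_independent_product_counts(self):
        t = np.outer([1, 2, 3, 4], [4, 3, 2, 1]).astype(float)
        assert mutual_information(t) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_two_state_coupling(self):
        t = np.zeros((4, 4))
        t[0, 0] = t[1, 1] = 500
        assert mutual_information(t) == pytest.approx(np.log(2))

    def test_stirling_limit_matches_logR(self):
        """R_ij ~ exp(n I_ij) for large n on perfectly coupled columns."""
        n = 10_000
        t = np.zeros((2, 2, 4, 4))
        t[0, 1][0, 0] = t[0, 1][1, 1] = n / 2
        t[1, 0] = t[0, 1].T
        pc = PairCountTensor(t)
        logR = dependency_log_ratio(pc, 0, 1)
        mi = mutual_information(pc.pair(0, 1))
        assert abs(logR / (n * mi) - 1) < 0.05


class TestContainers:
    def test_count_profile_rejects_unequal_totals(self):
        with pytest.raises(ValueError):
            CountProfile(np.array([[1, 1, 1, 1], [2, 2, 2, 2.0]]))

    def test_pair_tensor_marginal_consistency_validation(self):
        pc = PairCountTensor.from_sites(["ACG", "AGG", "TCG"])
        pc.validate()
        broken = pc.tensor.copy()
        broken[0, 1, 0, 1] += 1.0
        with pytest.raises(ValueError):
            PairCountTensor(broken).validate()

    def test_fractional_weights_supported(self):
        pc = PairCountTensor.from_sites(["AC", "GT"], weights=[0.25, 0.75])
        assert pc.n == pytest.approx(1.0)
        assert pc.marginal_profile().counts[0] == pytest.approx(
            [0.25, 0, 0.75, 0])


class TestEncoding:
    def test_roundtrip_and_case_folding(self):
        assert list(encode("acgtN")) == [0, 1, 2, 3, 4]

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="X"):
            encode("ACXGT")

    def test_revcomp_keeps_n(self):
        assert list(revcomp_codes(encode("ACNGT"))) == list(encode("ACNGT"))
        assert list(revcomp_codes(encode("AACG"))) == list(encode("CGTT"))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=200), min_size=4,
                max_size=4))
def test_column_log_prob_is_nonpositive_for_nonempty(counts):
    val = column_log_prob(np.array(counts))
    assert val <= 1e-12
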