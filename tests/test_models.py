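"""PSWM / ADJ / DWT predictives, energies, and strand symmetry."""

import numpy as np
import pytest

from dwt.counts import PairCountTensor, decode, encode, revcomp_codes
from dwt.models import (
    AdjModel,
    BackgroundModel,
    DwtModel,
    PswmModel,
    pad_with_n,
    segment_energy,
    sequence_energy,
)

from conftest import all_sequences, random_site_tensor


def _models_from_sites(sites):
    pairs = PairCountTensor.from_sites(sites)
    return (PswmModel(pairs.marginal_profile()), AdjModel(pairs),
            DwtModel(pairs))


class TestPswmPredictive:
    def test_prior_only_is_uniform(self):
        m = PswmModel.from_counts(np.zeros((4, 4)))
        assert m.log_predictive_one("ACGT") == pytest.approx(4 * np.log(0.25))

    def test_worked_counts(self):
        counts = np.zeros((3, 4))
        counts[:, 0] = 2.0
        m = PswmModel.from_counts(counts)
        assert m.log_predictive_one("AAA") == pytest.approx(3 * np.log(0.625))

    def test_length_mismatch(self):
        m = PswmModel.from_counts(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            m.log_predictive_one("ACG")

    def test_predictive_rows_sum_to_one(self, rng):
        m = PswmModel.from_counts(20 * rng.dirichlet(np.ones(4), size=6))
        np.testing.assert_allclose(m.predictive_probs().sum(axis=1), 1.0)


class TestNormalization:
    """The central correctness gate: sum_s P(s|S) = 1 for every model."""

    @pytest.mark.parametrize("l", [2, 3, 4, 5])
    def test_exhaustive_normalization(self, rng, l):
        pairs = random_site_tensor(rng, l, n=50)
        seqs = all_sequences(l)
        for model in (PswmModel(pairs.marginal_profile()), AdjModel(pairs),
                      DwtModel(pairs)):
            total = np.exp(model.log_predictive(seqs)).sum()
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalization_with_coupled_counts(self, rng):
        from dwt.simulate import chain_motif
        sites = chain_motif(l=4, agree=0.9).sample(100, rng)
        seqs = all_sequences(4)
        for model in _models_from_sites(sites):
            assert np.exp(model.log_predictive(seqs)).sum() == \
                pytest.approx(1.0, abs=1e-6)


class TestDwtReductions:
    def test_prior_only_reduces_to_pswm(self):
        d = DwtModel(PairCountTensor(np.zeros((4, 4, 4, 4))))
        p = PswmModel.from_counts(np.zeros((4, 4)))
        seqs = all_sequences(4)
        np.testing.assert_allclose(d.log_predictive(seqs),
                                   p.log_predictive(seqs), atol=1e-10)

    def test_uniform_outer_product_counts_reduce_to_pswm(self):
        """Uniform columns with product pair counts carry no dependency
        information at any n, including fractional n <= 1."""
        for n in (0.5, 1.0, 8.0):
            t = np.full((4, 4, 4, 4), n / 16)
            for i in range(4):
                t[i, i] = 0.0
            d = DwtModel(PairCountTensor(t))
            seqs = all_sequences(4)
            np.testing.assert_allclose(d.log_predictive(seqs),
                                       d.to_pswm().log_predictive(seqs),
                                       atol=1e-10)

    def test_single_site_model_prefers_its_site(self):
        d = DwtModel.from_sites(["ACGT"])
        own = d.log_predictive_one("ACGT")
        for i in range(4):
            for a in "ACGT":
                s = list("ACGT")
                if s[i] == a:
                    continue
                s[i] = a
                assert d.log_predictive_one("".join(s)) < own

    def test_adj_equals_dwt_for_l2(self, rng):
        pairs = random_site_tensor(rng, 2, n=40)
        seqs = all_sequences(2)
        np.testing.assert_allclose(AdjModel(pairs).log_predictive(seqs),
                                   DwtModel(pairs).log_predictive(seqs),
                                   rtol=1e-12)

    def test_adj_outer_product_reduces_to_pswm(self):
        t = np.full((3, 3, 4, 4), 1.0 / 16)
        for i in range(3):
            t[i, i] = 0.0
        a = AdjModel(PairCountTensor(t))
        seqs = all_sequences(3)
        np.testing.assert_allclose(a.log_predictive(seqs),
                                   a.to_pswm().log_predictive(seqs),
                                   atol=1e-10)

    def test_coupled_model_beats_pswm_on_held_out_sites(self, rng):
        """Mean held-out log-predictive: DWT > PSWM under true coupling."""
        from dwt.simulate import two_edge_distal_motif
        planted = two_edge_distal_motif()
        wins = 0
        reps = 20
        for r in range(reps):
            rr = np.random.default_rng(1000 + r)
            train = planted.sample(500, rr)
            test = planted.sample(100, rr)
            pairs = PairCountTensor.from_sites(train)
            d, p = DwtModel(pairs), PswmModel(pairs.marginal_profile())
            if d.log_predictive(test).mean() > p.log_predictive(test).mean():
                wins += 1
        assert wins >= reps * 0.95


class TestNHandling:
    def test_all_n_segment_is_energy_neutral(self, rng):
        pairs = random_site_tensor(rng, 4, n=30)
        bg = BackgroundModel(np.array([0.4, 0.2, 0.2, 0.2]))
        for model in (PswmModel(pairs.marginal_profile()), AdjModel(pairs),
                      DwtModel(pairs)):
            assert segment_energy(model, bg, "NNNN") == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_n_positions_marginalized_consistently(self, rng):
        """An N at one position leaves the other positions' PSWM terms."""
        pairs = random_site_tensor(rng, 3, n=30)
        p = PswmModel(pairs.marginal_profile())
        full = p.log_predictive_one("ACG")
        with_n = p.log_predictive_one("ANG")
        colpred = np.log(p.predictive_probs())
        assert full - with_n == pytest.approx(colpred[1, 1], rel=1e-10)


class TestSequenceEnergy:
    def test_single_segment_palindrome_doubles(self):
        # palindromic site on a palindromic model: both strands identical
        sites = ["ACGT", "AAGT", "ACTT"]
        sites = sites + [decode(revcomp_codes(encode(s))) for s in sites]
        d = DwtModel.from_sites(sites)
        bg = BackgroundModel.uniform()
        prof = sequence_energy(d, bg, "ACGT")
        assert prof.l_s == 2
        assert prof.total == pytest.approx(
            segment_energy(d, bg, "ACGT") + np.log(2), rel=1e-10)

    def test_total_bounds_best_segment(self, rng):
        pairs = random_site_tensor(rng, 5, n=30)
        d = DwtModel(pairs)
        bg = BackgroundModel(np.array([0.3, 0.2, 0.3, 0.2]))
        prof = sequence_energy(d, bg, "ACGTTGACAGT")
        assert prof.total >= prof.energies.max()
        assert prof.l_s == 2 * (11 - 5 + 1)

    def test_reverse_complement_consistency(self, rng):
        pairs = random_site_tensor(rng, 4, n=30)
        d = DwtModel(pairs)
        bg = BackgroundModel(np.array([0.35, 0.15, 0.15, 0.35]))
        s = "ACGGTTACAG"
        rc = decode(revcomp_codes(encode(s)))
        assert sequence_energy(d, bg, s).total == pytest.approx(
            sequence_energy(d, bg, rc).total, rel=1e-10)

    def test_too_short_without_padding(self, rng):
        d = DwtModel(random_site_tensor(rng, 6, n=10))
        bg = BackgroundModel.uniform()
        with pytest.raises(ValueError):
            sequence_energy(d, bg, "ACG")
        prof = sequence_energy(d, bg, "ACG", pad=True)
        assert prof.l_s == 2 * (3 + 2 * 3 - 6 + 1)

    def test_spacer_concatenation_bound(self, rng):
        """Energies of a spacer-joined pair stay within the log-sum-exp of
        the parts plus N-neutral spacer-spanning terms."""
        pairs = random_site_tensor(rng, 3, n=20)
        d = DwtModel(pairs)
        bg = BackgroundModel.uniform()
        s1, s2 = "ACGTA", "GGTAC"
        joined = s1 + "NN" + s2
        e1 = sequence_energy(d, bg, s1)
        e2 = sequence_energy(d, bg, s2)
        ej = sequence_energy(d, bg, joined)
        assert ej.total >= np.logaddexp(e1.total, e2.total) - 1e-10

    def test_background_from_sequences(self):
        bg = BackgroundModel.from_sequences(["AACC", "GGTT"])
        np.testing.assert_allclose(bg.freqs, 0.25, atol=0.05)

    def test_pad_with_n(self):
        assert pad_with_n("ACGT", 2) == "NNACGTNN"
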