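"""EM motif inference: likelihood, E0 optimization, posteriors, updates."""

import numpy as np
import pytest

from dwt.counts import CountProfile
from dwt.em import (
    MotifEM,
    SegmentIndex,
    dataset_log_likelihood,
    optimize_e0,
    run_em,
    site_posteriors,
    update_pair_counts,
)
from dwt.models import BackgroundModel, PswmModel
from dwt.simulate import embed_in_background, null_motif, sample_sites

BG = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]))


def _toy_peaks(n=60, length=60, seed=0, planted=None):
    planted = planted or null_motif(l=6, strength=0.85)
    sites = sample_sites(planted, n, seed)
    seqs, _ = embed_in_background(sites, length, BG, seed + 1)
    return sites, seqs


class TestDatasetLogLikelihood:
    def test_degenerate_identity(self):
        # E(S) = 0, L_S = 1: numerator equals denominator at any E0
        e = np.zeros(5)
        ls = np.ones(5)
        for e0 in (-3.0, 0.0, 4.0):
            assert dataset_log_likelihood(e, ls, e0) == pytest.approx(0.0)

    def test_limit_e0_to_minus_inf(self):
        e = np.array([1.0, 2.0, 3.0])
        ls = np.full(3, 10.0)
        assert dataset_log_likelihood(e, ls, -200.0) == pytest.approx(e.sum())

    def test_closed_form_toy(self):
        e = np.array([1.0, 2.0, 3.0])
        ls = np.full(3, 10.0)
        want = sum(np.log((np.exp(x) + 10 * np.exp(0.0)) / (1 + np.exp(0.0)))
                   for x in e)
        assert dataset_log_likelihood(e, ls, 0.0) == pytest.approx(want)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            dataset_log_likelihood(np.array([]), np.array([]), 0.0)


class TestOptimizeE0:
    def test_degenerate_returns_zero(self):
        ls = np.full(4, 7.0)
        e = np.log(ls)
        assert optimize_e0(e, ls) == 0.0

    def test_matches_grid_search(self, rng):
        for _ in range(5):
            e = rng.normal(3.0, 2.0, 20)
            ls = np.full(20, 100.0)
            e0 = optimize_e0(e, ls)
            grid = np.linspace(-50, 50, 100_001)
            lls = np.array([dataset_log_likelihood(e, ls, x) for x in
                            np.linspace(e0 - 0.5, e0 + 0.5, 2001)])
            assert dataset_log_likelihood(e, ls, e0) >= lls.max() - 1e-9

    def test_single_sequence_root(self):
        e = np.array([5.0])
        ls = np.array([100.0])
        e0 = optimize_e0(e, ls)
        grid = np.linspace(-50, 50, 100_001)
        lls = np.array([dataset_log_likelihood(e, ls, x) for x in grid])
        best = grid[np.argmax(lls)]
        assert abs(e0 - best) < 1e-3 or dataset_log_likelihood(e, ls, e0) >= \
            lls.max() - 1e-6

    def test_local_optimality(self, rng):
        e = rng.normal(6.0, 1.5, 30)
        ls = np.full(30, 50.0)
        e0 = optimize_e0(e, ls)
        if -50 < e0 < 50:  # interior root
            L = dataset_log_likelihood(e, ls, e0)
            assert L >= dataset_log_likelihood(e, ls, e0 + 0.01) - 1e-9
            assert L >= dataset_log_likelihood(e, ls, e0 - 0.01) - 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            optimize_e0(np.array([np.nan]), np.array([2.0]))


class TestSitePosteriors:
    def test_toy_arithmetic(self):
        e_seg = np.array([0.0, np.log(3.0)])
        e_tot = np.array([np.log(4.0)])  # logsumexp of the segments
        ls = np.array([2.0])
        seq_ids = np.array([0, 0])
        p = site_posteriors(e_seg, e_tot, ls, 0.0, seq_ids)
        np.testing.assert_allclose(p, [1 / 6, 3 / 6], rtol=1e-12)
        assert p.sum() == pytest.approx(4 / 6)

    def test_sum_identity(self, rng):
        """sum_s P_b(s) = e^{E(S)} / (e^{E(S)} + L_S e^{E0}) exactly."""
        _, seqs = _toy_peaks()
        idx = SegmentIndex(seqs, 6)
        scorer = PswmModel.from_counts(5 * rng.dirichlet(np.ones(4), size=6))
        e_seg, e_tot = idx.energies(scorer, BG)
        e0 = -1.0
        p = site_posteriors(e_seg, e_tot, idx.l_s, e0, idx.seq_ids)
        got = np.add.reduceat(p, idx.starts)
        want = np.exp(e_tot - np.logaddexp(e_tot, np.log(idx.l_s * 1.0) + e0))
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_dominant_site_limit(self):
        e_seg = np.array([10.0, -5.0])
        e_tot = np.array([np.logaddexp(10.0, -5.0)])
        p = site_posteriors(e_seg, e_tot, np.array([2.0]), -200.0,
                            np.array([0, 0]))
        assert p[0] == pytest.approx(1.0, abs=1e-6)


class TestPairCountUpdates:
    def test_single_certain_segment_gives_indicator(self):
        idx = SegmentIndex(["ACGT"], 4)
        post = np.array([1.0, 0.0])  # forward segment only
        t = update_pair_counts(idx, post).tensor
        assert t[0, 1, 0, 1] == 1.0  # A at 1, C at 2
        assert t[2, 3, 2, 3] == 1.0  # G at 3, T at 4
        assert t.sum() == pytest.approx(4 * 3)  # l(l-1) populated cells

    def test_zero_posteriors_zero_tensor(self):
        idx = SegmentIndex(["ACGTA"], 4)
        t = update_pair_counts(idx, np.zeros(idx.segments.shape[0])).tensor
        assert t.sum() == 0.0

    def test_convex_combination_of_indicators(self):
        idx = SegmentIndex(["ACGT"], 4)
        post = np.array([0.25, 0.75])  # forward + its reverse complement
        t = update_pair_counts(idx, post)
        fwd = update_pair_counts(idx, np.array([1.0, 0.0])).tensor
        rc = update_pair_counts(idx, np.array([0.0, 1.0])).tensor
        np.testing.assert_allclose(t.tensor, 0.25 * fwd + 0.75 * rc)

    def test_mass_conservation_across_pairs(self, rng):
        _, seqs = _toy_peaks(n=20)
        idx = SegmentIndex(seqs, 6)
        post = rng.random(idx.segments.shape[0]) * 0.01
        t = update_pair_counts(idx, post).tensor
        masses = [t[i, j].sum() for i in range(6) for j in range(6) if i != j]
        np.testing.assert_allclose(masses, post.sum(), rtol=1e-9)

    def test_reverse_strand_contributes_revcomp_letters(self):
        idx = SegmentIndex(["AACG"], 4)
        # the reverse-complement segment of AACG is CGTT
        t = update_pair_counts(idx, np.array([0.0, 1.0])).tensor
        assert t[0, 1, 1, 2] == 1.0  # C then G
        assert t[2, 3, 3, 3] == 1.0  # T then T


class TestRunEm:
    def test_monotone_likelihood_trace(self):
        sites, seqs = _toy_peaks(n=40)
        init = CountProfile.from_sites(sites[:20]).counts
        for kind in ("pswm", "adj", "dwt"):
            res = run_em(seqs, init, model_kind=kind, tol=1e-6, max_iter=15)
            tr = res.trace["log_likelihood"].to_numpy()
            diffs = np.diff(tr)
            assert (diffs >= -1e-6 * np.abs(tr[1:])).all(), kind

    def test_fixed_point_when_counts_match_data(self):
        """Soft counts equal to the model's counts change < 1e-8 in one
        iteration once EM has converged."""
        sites, seqs = _toy_peaks(n=40)
        init = CountProfile.from_sites(sites[:20]).counts
        res = run_em(seqs, init, model_kind="dwt", tol=1e-12, max_iter=60)
        model = res.model
        idx = SegmentIndex(seqs, 6)
        bg = BackgroundModel.from_sequences(seqs)
        e_seg, e_tot = idx.energies(model, bg)
        e0 = optimize_e0(e_tot, idx.l_s)
        post = site_posteriors(e_seg, e_tot, idx.l_s, e0, idx.seq_ids)
        new = update_pair_counts(idx, post).tensor
        rel = np.abs(new - model.pairs.tensor).max() / max(model.pairs.n, 1)
        assert rel < 1e-4  # one extra iteration barely moves the counts

    def test_motif_longer_than_sequences_rejected(self):
        with pytest.raises(ValueError):
            run_em(["ACGT"], np.zeros((10, 4)))

    def test_restarts_deterministic_given_seed(self):
        sites, seqs = _toy_peaks(n=20)
        init = CountProfile.from_sites(sites[:10]).counts
        r1 = run_em(seqs, init, model_kind="pswm", restarts=2, random_state=5,
                    max_iter=5)
        r2 = run_em(seqs, init, model_kind="pswm", restarts=2, random_state=5,
                    max_iter=5)
        assert r1.log_likelihood == r2.log_likelihood


class TestMotifEMEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        est = MotifEM(model="pswm", init_pswm=np.zeros((4, 4)), max_iter=3)
        params = est.get_params()
        assert params["model"] == "pswm"
        est2 = clone(est)
        assert est2.get_params()["max_iter"] == 3
        est2.set_params(max_iter=7)
        assert est2.max_iter == 7

    def test_fit_predict_sites_and_score(self):
        sites, seqs = _toy_peaks(n=30)
        init = CountProfile.from_sites(sites[:15]).counts
        est = MotifEM(model="pswm", init_pswm=init, max_iter=10,
                      tol=1e-5).fit(seqs)
        assert est.model_.length == 6
        assert np.isfinite(est.e0_)
        energies = est.score_samples(seqs)
        assert energies.shape == (len(seqs),)
        df = est.predict_sites(seqs[:3])
        assert set(df.columns) >= {"seq_index", "offset", "strand", "energy",
                                   "posterior"}
        assert (df["posterior"] <= 1 + 1e-9).all()
        assert np.isfinite(est.score(seqs))

    def test_unfitted_raises(self):
        est = MotifEM(init_pswm=np.zeros((4, 4)))
        with pytest.raises(AttributeError):
            est.score_samples(["ACGT"])

    def test_requires_init_pswm(self):
        with pytest.raises(ValueError):
            MotifEM().fit(["ACGTACGT"])
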