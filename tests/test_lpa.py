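"""Mixture EM, model selection, classification error, distal estimators."""

import math

import numpy as np
import pandas as pd
import pytest

import hac24 as h
from hac24.lpa import MixtureFit, _sample_mixture


def two_class_data(n=400, sep=6.0, seed=2):
    """Two spherical classes `sep` SDs apart, with labels."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < 0.5).astype(int)
    Y = rng.normal(size=(n, 2)) + sep * labels[:, None]
    return Y, labels


class TestFitLpa:
    def test_one_class_closed_form(self, rng):
        Y = rng.normal(size=(60, 3))
        fit = h.fit_lpa(Y, 1)
        np.testing.assert_allclose(fit.means[0], Y.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(fit.covariances[0],
                                   np.cov(Y, rowvar=False, ddof=0), atol=1e-10)

    def test_separated_classes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        Y, labels = two_class_data()
        fit = h.fit_lpa(Y, 2, n_starts=8, seed=3)
        assign = h.modal_assign(fit)
        ari = adjusted_rand_score(labels, assign)
        assert ari > 0.95
        # class means within 3 SE of the true centroids (after matching)
        perm = h.lpa.match_labels(fit, np.array([[0.0, 0.0], [6.0, 6.0]]))
        for k in (0, 1):
            nk = fit.weights[perm[k]] * fit.n
            se = 1.0 / math.sqrt(nk)
            assert np.all(np.abs(fit.means[perm[k]] - 6.0 * k) < 3 * se)

    def test_same_seed_reproduces_solution(self):
        Y, _ = two_class_data()
        f1 = h.fit_lpa(Y, 2, n_starts=5, seed=9)
        f2 = h.fit_lpa(Y, 2, n_starts=5, seed=9)
        np.testing.assert_array_equal(f1.posteriors, f2.posteriors)
        assert f1.log_likelihood == f2.log_likelihood

    def test_loglik_matches_sklearn_oracle(self):
        """Independent cross-check: sklearn's GaussianMixture reaches the
        same optimum on well-separated data."""
        from sklearn.mixture import GaussianMixture

        Y, _ = two_class_data()
        ours = h.fit_lpa(Y, 2, n_starts=8, seed=3)
        gm = GaussianMixture(2, covariance_type="full", n_init=4,
                             reg_covar=1e-6, random_state=0, tol=1e-8,
                             max_iter=500).fit(Y)
        assert ours.log_likelihood / len(Y) == pytest.approx(
            gm.score(Y), abs=1e-4)
        perm = h.lpa.match_labels(ours, gm.means_)
        np.testing.assert_allclose(ours.means[perm], gm.means_, atol=1e-2)

    def test_closed_composition_rejected(self, rng):
        X = rng.dirichlet(np.ones(4), size=50)
        with pytest.raises(ValueError, match="rank-deficient"):
            h.fit_lpa(X, 2, n_starts=2)

    def test_em_trace_monotone(self, act_cohort):
        table = act_cohort["table"]
        fit = h.fit_lpa(table[["sit", "stand", "step"]], 3, n_starts=6,
                        seed=5)
        diffs = np.diff(fit.trace)
        assert np.all(diffs >= -1e-6 * np.abs(fit.trace[:-1]))

    def test_posterior_rows_stochastic(self, act_cohort):
        table = act_cohort["table"]
        fit = h.fit_lpa(table[["sit", "stand", "step"]], 2, n_starts=4,
                        seed=6)
        np.testing.assert_allclose(fit.posteriors.sum(axis=1), 1.0,
                                   atol=1e-10)
        assert np.all(fit.posteriors >= 0)

    def test_mixture_mean_identity(self, act_cohort):
        table = act_cohort["table"]
        ind = table[["sit", "stand", "step"]]
        fit = h.fit_lpa(ind, 3, n_starts=6, seed=7)
        np.testing.assert_allclose(fit.weights @ fit.means,
                                   ind.to_numpy().mean(axis=0), atol=1e-6)


class TestSelectionStats:
    def make_fit(self, posteriors, ll=-100.0, n_params=5):
        P = np.asarray(posteriors, dtype=float)
        n, K = P.shape
        return MixtureFit(K=K, weights=np.full(K, 1 / K),
                          means=np.zeros((K, 2)),
                          covariances=np.stack([np.eye(2)] * K),
                          posteriors=P, log_likelihood=ll,
                          trace=np.array([ll]), n_params=n_params, n=n)

    def test_hard_posteriors_entropy_one(self):
        fit = self.make_fit([[1, 0], [0, 1], [1, 0]])
        assert h.selection_stats(fit).entropy == pytest.approx(1.0)

    def test_uniform_posteriors_entropy_zero(self):
        fit = self.make_fit(np.full((4, 2), 0.5))
        assert h.selection_stats(fit).entropy == pytest.approx(0.0)

    def test_one_class_entropy_missing(self, rng):
        fit = h.fit_lpa(rng.normal(size=(30, 2)), 1)
        assert h.selection_stats(fit).entropy is None

    def test_three_person_hand_case(self):
        """All criteria against long-hand arithmetic."""
        P = np.array([[0.8, 0.2], [0.6, 0.4], [0.9, 0.1]])
        ll, p, n = -42.0, 5, 3
        s = h.selection_stats(self.make_fit(P, ll, p))
        ent = -sum(q * math.log(q) for row in P for q in row)
        assert s.aic == pytest.approx(-2 * ll + 2 * p)
        assert s.bic == pytest.approx(-2 * ll + p * math.log(n))
        assert s.caic == pytest.approx(-2 * ll + p * (math.log(n) + 1))
        assert s.abic == pytest.approx(-2 * ll + p * math.log((n + 2) / 24))
        assert s.icl_bic == pytest.approx(s.bic + 2 * ent)
        assert s.entropy == pytest.approx(1 - ent / (n * math.log(2)))

    def test_selection_table_shape(self, act_cohort):
        ind = act_cohort["table"][["sit", "stand", "step"]]
        fits = {k: h.fit_lpa(ind, k, n_starts=4, seed=8) for k in (1, 2)}
        tab = h.selection_table(fits)
        assert list(tab["K"]) == [1, 2]
        assert {"AIC", "BIC", "CAIC", "aBIC", "ICL_BIC"} <= set(tab.columns)


class TestBootstrapLrt:
    def test_reproducible(self):
        Y, _ = two_class_data(n=120, sep=0.0, seed=5)
        kw = dict(reps=99, seed=11, n_starts=1, max_iter=30, tol=1e-5)
        r1 = h.bootstrap_lrt(Y, 2, **kw)
        r2 = h.bootstrap_lrt(Y, 2, **kw)
        assert r1["p_value"] == r2["p_value"]
        assert r1["lr_observed"] == r2["lr_observed"]

    def test_power_on_separated_classes(self):
        Y, _ = two_class_data(n=150, sep=6.0, seed=6)
        res = h.bootstrap_lrt(Y, 2, reps=199, seed=12, n_starts=2,
                              max_iter=60, tol=1e-6)
        assert res["p_value"] < 0.05

    def test_requires_99_reps(self):
        Y, _ = two_class_data(n=60)
        with pytest.raises(ValueError):
            h.bootstrap_lrt(Y, 2, reps=50)


class TestModalAssignment:
    def make_fit(self, P):
        P = np.asarray(P, dtype=float)
        n, K = P.shape
        return MixtureFit(K=K, weights=np.full(K, 1 / K),
                          means=np.zeros((K, 2)),
                          covariances=np.stack([np.eye(2)] * K),
                          posteriors=P, log_likelihood=0.0,
                          trace=np.array([0.0]), n_params=1, n=n)

    def test_highest_posterior_wins(self):
        fit = self.make_fit([[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_array_equal(h.modal_assign(fit), [0, 1])

    def test_tie_breaks_low_index(self, caplog):
        import logging

        fit = self.make_fit([[0.5, 0.5]])
        with caplog.at_level(logging.INFO, logger="hac24.lpa"):
            labels = h.modal_assign(fit)
        assert labels[0] == 0
        assert any("tie" in r.message for r in caplog.records)

    def test_perfect_separation_recovers_truth(self):
        Y, labels = two_class_data(sep=8.0)
        fit = h.fit_lpa(Y, 2, n_starts=6, seed=13)
        assign = h.modal_assign(fit)
        perm = h.lpa.match_labels(fit, np.array([[0.0, 0.0], [8.0, 8.0]]))
        mapped = np.array([int(np.where(perm == a)[0][0]) for a in assign])
        assert (mapped == labels).mean() == 1.0


class TestClassificationMatrix:
    def test_hard_posteriors_give_identity(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        fit = TestModalAssignment().make_fit(P)
        D = h.classification_matrix(fit)
        np.testing.assert_allclose(D, np.eye(2))

    def test_rows_sum_to_one(self, rng):
        P = rng.dirichlet(np.ones(3), size=40)
        fit = MixtureFit(K=3, weights=np.full(3, 1 / 3),
                         means=np.zeros((3, 2)),
                         covariances=np.stack([np.eye(2)] * 3),
                         posteriors=P, log_likelihood=0.0,
                         trace=np.array([0.0]), n_params=1, n=40)
        D = h.classification_matrix(fit)
        np.testing.assert_allclose(D.sum(axis=1), 1.0, atol=1e-12)

    def test_four_person_hand_case(self):
        P = np.array([[0.7, 0.3], [0.6, 0.4], [0.2, 0.8], [0.4, 0.6]])
        fit = TestModalAssignment().make_fit(P)
        a = h.modal_assign(fit)     # [0, 0, 1, 1]
        D = h.classification_matrix(fit, a)
        col0 = P[:2].sum(axis=0)    # assigned to class 0
        col1 = P[2:].sum(axis=0)
        denom = P.sum(axis=0)
        np.testing.assert_allclose(D[:, 0], col0 / denom)
        np.testing.assert_allclose(D[:, 1], col1 / denom)


@pytest.fixture(scope="module")
def overlap_sim():
    """Two overlapping classes with a known outcome gap, fitted mixture,
    assignment and error matrix — the inputs of the distal estimators."""
    rng = np.random.default_rng(17)
    n = 1500
    labels = (rng.random(n) < 0.5).astype(int)
    Y = rng.normal(size=(n, 2)) + 2.0 * labels[:, None]   # moderate overlap
    truth = 1.0
    y = 0.3 + truth * labels + rng.normal(0, 0.5, n)
    fit = h.fit_lpa(Y, 2, n_starts=6, seed=18)
    perm = h.lpa.match_labels(fit, np.array([[0.0, 0.0], [2.0, 2.0]]))
    # reorder classes so class 1 is the shifted one
    order = np.argsort(perm)
    fit = MixtureFit(K=2, weights=fit.weights[order], means=fit.means[order],
                     covariances=fit.covariances[order],
                     posteriors=fit.posteriors[:, order],
                     log_likelihood=fit.log_likelihood, trace=fit.trace,
                     n_params=fit.n_params, n=fit.n)
    assign = h.modal_assign(fit)
    D = h.classification_matrix(fit, assign)
    return {"labels": labels, "y": y, "truth": truth, "fit": fit,
            "assign": assign, "D": D}


class TestDistalEstimators:
    def test_naive_equals_mean_difference_without_covariates(self, overlap_sim):
        s = overlap_sim
        res = h.distal_naive(s["assign"], s["y"], K=2)
        diff = (s["y"][s["assign"] == 1].mean()
                - s["y"][s["assign"] == 0].mean())
        assert res.effects["class_1"] == pytest.approx(diff, abs=1e-10)

    def test_naive_attenuated_bch_unbiased(self, overlap_sim):
        s = overlap_sim
        naive = h.distal_naive(s["assign"], s["y"], K=2)
        bch = h.distal_bch(s["fit"], s["assign"], s["D"], s["y"])
        assert abs(naive.effects["class_1"]) < s["truth"]
        assert abs(bch.effects["class_1"] - s["truth"]) < \
            3 * bch.robust_se["class_1"]
        assert abs(bch.effects["class_1"]) > abs(naive.effects["class_1"])
        assert bch.robust_se["class_1"] > naive.robust_se["class_1"]

    def test_bch_equals_naive_for_identity_D(self, overlap_sim):
        s = overlap_sim
        naive = h.distal_naive(s["assign"], s["y"], K=2)
        bch = h.distal_bch(s["fit"], s["assign"], np.eye(2), s["y"])
        np.testing.assert_allclose(bch.effects.to_numpy(),
                                   naive.effects.to_numpy(), atol=1e-10)

    def test_bch_weights_sum_to_one(self, overlap_sim):
        Dinv = np.linalg.inv(overlap_sim["D"])
        np.testing.assert_allclose(Dinv.sum(axis=1), 1.0, atol=1e-10)

    def test_ill_conditioned_D_rejected(self, overlap_sim):
        s = overlap_sim
        D_bad = np.array([[0.5, 0.5], [0.5, 0.5]]) + 1e-9 * np.eye(2)
        with pytest.raises(ValueError, match="ill-conditioned"):
            h.distal_bch(s["fit"], s["assign"], D_bad, s["y"])

    def test_ml_matches_naive_for_identity_D(self, overlap_sim):
        s = overlap_sim
        naive = h.distal_naive(s["assign"], s["y"], K=2)
        ml = h.distal_ml(s["fit"], s["assign"], np.eye(2), s["y"])
        assert ml.effects["class_1"] == pytest.approx(
            naive.effects["class_1"], abs=0.02)

    def test_ml_recovers_truth_and_agrees_with_bch(self, overlap_sim):
        s = overlap_sim
        bch = h.distal_bch(s["fit"], s["assign"], s["D"], s["y"])
        ml = h.distal_ml(s["fit"], s["assign"], s["D"], s["y"])
        assert abs(ml.effects["class_1"] - s["truth"]) < \
            3 * ml.robust_se["class_1"]
        assert ml.effects["class_1"] == pytest.approx(
            bch.effects["class_1"], abs=0.1)

    def test_ml_predictor_null_covariate(self, overlap_sim):
        """A covariate independent of class membership shows no
        class-predicting effect."""
        s = overlap_sim
        rng = np.random.default_rng(23)
        x = rng.normal(size=len(s["y"]))
        res = h.distal_ml(s["fit"], s["assign"], s["D"], x, role="predictor")
        assert res.wald_global_p > 0.01

    def test_ml_predictor_detects_real_covariate(self, overlap_sim):
        s = overlap_sim
        rng = np.random.default_rng(24)
        x = s["labels"] + rng.normal(0, 0.5, len(s["y"]))
        res = h.distal_ml(s["fit"], s["assign"], s["D"], x, role="predictor")
        assert res.wald_global_p < 0.001

    def test_empty_reference_rejected(self, overlap_sim):
        s = overlap_sim
        with pytest.raises(ValueError, match="reference"):
            h.distal_naive(np.ones(10, dtype=int), np.zeros(10), K=2,
                           reference=0)


class TestSampleMixture:
    def test_matches_fit_moments(self, rng):
        fit = MixtureFit(K=2, weights=np.array([0.3, 0.7]),
                         means=np.array([[0.0, 0.0], [4.0, 4.0]]),
                         covariances=np.stack([np.eye(2)] * 2),
                         posteriors=np.ones((1, 2)) / 2,
                         log_likelihood=0.0, trace=np.array([0.0]),
                         n_params=1, n=1)
        Y = _sample_mixture(fit, 20_000, rng)
        assert Y.mean(axis=0) == pytest.approx([2.8, 2.8], abs=0.06)
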