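"""Constrained-EM mixture: closed forms, oracles, selection and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from shockdtr.mixture import (MixtureFit, bootstrap_lrt, characterize_classes,
                              fit_fmm, membership_stability, mixture_metrics,
                              predict_classes, select_num_classes,
                              transition_table)
from shockdtr.preprocess import build_feature_matrix
from shockdtr.synthetic import default_profiles, generate_cohort

from conftest import two_cluster_data


class TestFitFmm:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 4)) * [1.0, 2.0, 0.5, 3.0] + [0, 1, 2, 3]
        fit = fit_fmm(X, K=1, n_starts=1, seed=0)
        assert np.allclose(fit.means[0], X.mean(axis=0), atol=1e-8)
        assert np.allclose(fit.shared_variances, X.var(axis=0), atol=1e-8)
        ll = norm.logpdf(X, loc=X.mean(0), scale=X.std(0)).sum()
        assert fit.loglik == pytest.approx(ll, abs=1e-6)
        assert fit.n_params == 4 + 4 + 0

    def test_separated_clusters_recovered(self):
        X = two_cluster_data(n_per=150, d=3, sep=10.0, seed=1)
        fit = fit_fmm(X, K=2, n_starts=5, seed=2)
        centers = fit.means[np.argsort(fit.means[:, 0])]
        # at 10-SD separation the assignment is effectively hard, so the
        # component means must match the empirical cluster means
        assert np.allclose(centers[0], X[:150].mean(axis=0), atol=0.02)
        assert np.allclose(centers[1], X[150:].mean(axis=0), atol=0.02)
        assert np.allclose(centers, [[0, 0, 0], [10, 0, 0]], atol=0.35)

    def test_loglik_path_monotone(self, small_matrix):
        fit = fit_fmm(small_matrix, K=4, n_starts=3, seed=5)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-7 * np.abs(fit.loglik_path[:-1])).all()

    def test_posterior_rows_normalized_and_weights_fixed_point(self, small_matrix):
        fit = fit_fmm(small_matrix, K=3, n_starts=3, tol=1e-12, max_iter=2000, seed=6)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fit.posteriors.mean(axis=0), fit.mixing_weights, atol=1e-6)
        assert (fit.shared_variances > 0).all()

    def test_estep_matches_pointwise_bayes_oracle(self):
        """One E-step equals a direct per-point Bayes-rule computation."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 2)) + np.where(rng.random((15, 1)) < 0.5, 0, 4)
        means = np.array([[0.0, 0.0], [4.0, 0.5]])
        variances = np.array([1.3, 0.8])
        weights = np.array([0.4, 0.6])
        fit = MixtureFit(K=2, means=means, shared_variances=variances,
                         mixing_weights=weights, loglik=np.nan,
                         posteriors=np.empty((0, 2)), converged=True, n_iter=0,
                         loglik_path=np.empty(0))
        resp, ll = fit.responsibilities(X)
        for i, x in enumerate(X):
            num = np.array([w * np.prod(norm.pdf(x, m, np.sqrt(variances)))
                            for w, m in zip(weights, means)])
            assert np.allclose(resp[i], num / num.sum(), atol=1e-10)
        assert np.isfinite(ll)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_fmm(np.zeros((3, 2)), K=3)


class TestMixtureMetrics:
    def _dummy_fit(self, loglik, n, K, d, posteriors=None):
        post = posteriors if posteriors is not None else np.full((n, K), 1.0 / K)
        return MixtureFit(K=K, means=np.zeros((K, d)), shared_variances=np.ones(d),
                          mixing_weights=np.full(K, 1.0 / K), loglik=loglik,
                          posteriors=post, converged=True, n_iter=1,
                          loglik_path=np.array([loglik]))

    def test_aic_formula(self):
        fit = self._dummy_fit(-100.0, n=50, K=2, d=4)  # n_params = 2*4+4+1 = 13
        aic, _, _ = mixture_metrics(fit)
        assert aic == pytest.approx(-2 * -100.0 + 2 * 13)

    def test_sabic_penalty_vanishes_at_n22(self):
        fit = self._dummy_fit(-100.0, n=22, K=2, d=4)
        _, sabic, _ = mixture_metrics(fit)
        assert sabic == pytest.approx(200.0)  # log((22+2)/24)=0

    def test_entropy_limits(self):
        onehot = np.zeros((30, 3)); onehot[np.arange(30), np.arange(30) % 3] = 1.0
        _, _, crisp = mixture_metrics(self._dummy_fit(-1.0, 30, 3, 2, onehot))
        assert crisp == pytest.approx(1.0)
        _, _, fuzzy = mixture_metrics(self._dummy_fit(-1.0, 30, 3, 2))
        assert fuzzy == pytest.approx(0.0)
        fit1 = self._dummy_fit(-1.0, 30, 1, 2, np.ones((30, 1)))
        assert mixture_metrics(fit1)[2] == 1.0  # K=1 convention


class TestBootstrapLrt:
    def test_clearly_separated_minimum_p(self):
        X = two_cluster_data(n_per=80, d=2, sep=10.0, seed=4)
        out = bootstrap_lrt(X, K=2, B=99, seed=0)
        assert out["p_value"] == pytest.approx(1.0 / 100.0)
        assert (out["lr_boot"] < out["lr_obs"]).all()

    def test_null_usually_nonsignificant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(5):
            X = rng.standard_normal((150, 2))
            p = bootstrap_lrt(X, K=2, B=19, seed=100 + rep)["p_value"]
            hits += p >= 0.05
        assert hits >= 4

    def test_p_in_unit_interval_and_guards(self):
        X = two_cluster_data(n_per=40, d=2, seed=5)
        p = bootstrap_lrt(X, K=2, B=5, seed=1)["p_value"]
        assert 0.0 < p <= 1.0
        with pytest.raises(ValueError):
            bootstrap_lrt(X, K=2, B=0)
        with pytest.raises(ValueError):
            bootstrap_lrt(X, K=1, B=5)


class TestSelectNumClasses:
    def test_single_candidate_two_cluster(self):
        X = two_cluster_data(n_per=120, d=3, sep=8.0, seed=6)
        rep = select_num_classes(X, K_range=[2], B=39, seed=0, n_starts=5)
        assert rep.chosen_K == 2

    def test_rare_class_disqualified_by_size_rule(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.standard_normal((980, 2)),
                       rng.standard_normal((20, 2)) + 12.0])  # 2% cluster
        rep = select_num_classes(X, K_range=[2], B=39, seed=1, n_starts=5)
        assert rep.chosen_K is None
        assert "class fraction" in rep.reasons[2]

    def test_five_class_recovery_reduced_scale(self):
        """Composite selection recovers the generating class count."""
        for seed in (101, 202, 303):
            cfg = default_profiles(n_patients=600, seed=seed)
            cohort, _ = generate_cohort(cfg)
            X, _ = build_feature_matrix(cohort)
            rep = select_num_classes(X, K_range=range(2, 8), B=39, seed=seed,
                                     n_starts=10)
            assert rep.chosen_K == 5, rep.table


class TestPredictClasses:
    def test_training_rows_keep_assignment(self, small_matrix):
        fit = fit_fmm(small_matrix, K=5, n_starts=5, seed=8)
        labels, post = predict_classes(fit, small_matrix)
        assert np.array_equal(labels - 1, fit.posteriors.argmax(axis=1))
        assert np.allclose(post, fit.posteriors, atol=1e-12)

    def test_midpoint_tie_goes_to_lowest_index(self):
        fit = MixtureFit(K=2, means=np.array([[0.0], [2.0]]),
                         shared_variances=np.array([1.0]),
                         mixing_weights=np.array([0.5, 0.5]), loglik=0.0,
                         posteriors=np.empty((0, 2)), converged=True, n_iter=0,
                         loglik_path=np.empty(0))
        labels, post = predict_classes(fit, np.array([[1.0]]))
        assert labels[0] == 1 and post[0, 0] == pytest.approx(0.5)

    def test_new_rows_from_one_profile(self, small_cohort, small_matrix):
        cfg, cohort, truth = small_cohort
        fit = fit_fmm(small_matrix, K=5, n_starts=10, seed=9)
        # map fitted component -> truth class by matching day-0 assignments
        labels, _ = predict_classes(fit, small_matrix)
        match = pd.crosstab(truth["true_class"], labels)
        comp_of_class3 = match.loc[3].idxmax()
        rng = np.random.default_rng(10)
        prof = cfg.class_profiles
        new = prof.centers[2] + rng.standard_normal((500, 17)) * prof.dispersions
        new_labels, _ = predict_classes(fit, pd.DataFrame(new, columns=list(small_matrix.columns)))
        assert (new_labels == comp_of_class3).mean() >= 0.90

    def test_column_mismatch_rejected(self, small_matrix):
        fit = fit_fmm(small_matrix, K=2, n_starts=2, seed=11)
        bad = small_matrix.rename(columns={"age": "years"})
        with pytest.raises(KeyError):
            predict_classes(fit, bad)


class TestCharacterizeClasses:
    def test_default_profile_names(self, small_cohort, small_matrix):
        cfg, _, truth = small_cohort
        fit = fit_fmm(small_matrix, K=5, n_starts=10, seed=9)
        labels, _ = predict_classes(fit, small_matrix)
        names = characterize_classes(fit)
        match = pd.crosstab(truth["true_class"], labels)
        assert names[match.loc[2].idxmax()] == "critical"
        assert names[match.loc[4].idxmax()] == "respiratory failure"
        assert names[match.loc[3].idxmax()] == "renal dysfunction"
        assert names[match.loc[5].idxmax()] == "mild"
        assert names[match.loc[1].idxmax()] == "baseline"
        assert sorted(names) == [1, 2, 3, 4, 5]

    def test_k1_is_baseline(self, small_matrix):
        fit = fit_fmm(small_matrix, K=1, n_starts=1, seed=1)
        assert characterize_classes(fit) == {1: "baseline"}


class TestTransitionTable:
    def test_static_labels_diagonal(self):
        labels = pd.DataFrame({"patient_id": np.repeat(range(10), 5),
                               "day": list([0, 1, 2, 3, 7]) * 10,
                               "label": 1})
        tabs = transition_table(labels, K=3)
        for tab in tabs.values():
            assert tab.loc[1, 1] == 10
            assert tab.to_numpy().sum() == 10

    def test_empirical_frequencies_match_generator(self, big_cohort):
        cfg, _, truth = big_cohort
        labels = truth.rename(columns={"true_class": "label"})
        tabs = transition_table(labels[["patient_id", "day", "label"]], K=5)
        for (d0, d1), tab in tabs.items():
            arr = tab.to_numpy()
            for i in range(5):
                row_n = arr[i].sum()
                if row_n < 100:
                    continue
                p_obs = arr[i] / row_n
                p_true = cfg.transition_matrix[i]
                sd = np.sqrt(p_true * (1 - p_true) / row_n)
                assert (np.abs(p_obs - p_true) < 3 * sd + 1e-9).all()

    def test_single_day_patient_contributes_nothing(self):
        labels = pd.DataFrame({"patient_id": [1, 2, 2], "day": [0, 0, 1],
                               "label": [2, 1, 1]})
        tabs = transition_table(labels, K=2)
        assert tabs[(0, 1)].to_numpy().sum() == 1  # only patient 2

    def test_duplicate_patient_day_rejected(self):
        labels = pd.DataFrame({"patient_id": [1, 1], "day": [0, 0], "label": [1, 2]})
        with pytest.raises(ValueError):
            transition_table(labels, K=2)


def test_membership_stability_modes(small_matrix):
    fit = fit_fmm(small_matrix, K=3, n_starts=3, seed=12)
    assert membership_stability(fit, per_row=True) <= membership_stability(fit)


def test_model_persistence_roundtrip(small_matrix, tmp_path):
    fit = fit_fmm(small_matrix, K=3, n_starts=3, seed=13)
    path = tmp_path / "model.json"
    fit.to_json(path)
    back = MixtureFit.from_json(str(path))
    new_labels, _ = predict_classes(back, small_matrix)
    old_labels, _ = predict_classes(fit, small_matrix)
    assert np.array_equal(new_labels, old_labels)
    assert back.feature_names == fit.feature_names
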