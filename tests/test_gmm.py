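"""E-M fitting, posteriors, BIC model search and component labeling."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

import sonartex as st
from sonartex.gmm import (
    GmmModel,
    bic_model_search,
    classify_gmm,
    fit_gmm,
    interpolated_means,
    label_components,
    posterior,
)
from sonartex.signatures import CalibrationMatrix
from sonartex.synth import simulate_feature_mixture


def naive_posterior(model, v):
    """Independent density-summation oracle for the responsibilities."""
    covs = model.full_covariances()
    dens = np.array(
        [
            model.weights[k] * multivariate_normal.pdf(v, model.means[k], covs[k])
            for k in range(model.q)
        ]
    )
    return dens / dens.sum()


def two_bump_data(seed=0, n=1000):
    X, labels = simulate_feature_mixture(
        [(np.array([0.0]), np.array([[1.0]]), 0.5),
         (np.array([10.0]), np.array([[1.0]]), 0.5)],
        n=n, seed=seed,
    )
    return X, labels


class TestFitGmm:
    def test_single_component_recovers_sample_moments(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.3], [0.0, 0.5]])
        m = fit_gmm(X, q=1, structure="full", seed=0)
        np.testing.assert_allclose(m.means[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            m.covariances[0], np.cov(X.T, ddof=0) + 1e-6 * np.eye(2), atol=1e-6
        )
        assert m.weights[0] == 1.0

    def test_separated_components_recovered(self):
        X, _ = two_bump_data(seed=1)
        m = fit_gmm(X, q=2, structure="full", seed=0)
        means = np.sort(m.means.ravel())
        assert abs(means[0] - 0.0) < 0.2
        assert abs(means[1] - 10.0) < 0.2

    def test_mean_initialization_keeps_component_order(self):
        X, _ = two_bump_data(seed=2)
        m = fit_gmm(X, q=2, init="means", init_means=np.array([[0.5], [9.5]]))
        assert m.means[0, 0] < m.means[1, 0]

    def test_tied_structure_shares_one_covariance(self):
        X, _ = two_bump_data(seed=3)
        m = fit_gmm(X, q=2, structure="tied", seed=0)
        assert m.covariances.shape == (1, 1)  # one D x D matrix, not per-q
        full = m.full_covariances()
        np.testing.assert_allclose(full[0], full[1])

    def test_loglik_nondecreasing_and_converged(self):
        # a decrease raises inside fit_gmm; convergence flag set
        X, _ = two_bump_data(seed=4)
        m = fit_gmm(X, q=2, structure="diag", seed=5)
        assert m.converged
        assert np.isfinite(m.log_likelihood)

    def test_structure_nesting_likelihood_order(self):
        X, _ = two_bump_data(seed=6)
        X2 = np.column_stack([X[:, 0], X[:, 0] * 0.5 + np.random.default_rng(1).normal(size=len(X))])
        lls = {
            s: fit_gmm(X2, q=2, structure=s, init="means",
                       init_means=np.array([[0.0, 0.0], [10.0, 5.0]])).log_likelihood
            for s in ("full", "diag", "spherical")
        }
        assert lls["full"] >= lls["diag"] - 1e-6
        assert lls["diag"] >= lls["spherical"] - 1e-6

    def test_agrees_with_sklearn_on_separated_data(self):
        X, _ = two_bump_data(seed=7)
        ours = fit_gmm(X, q=2, structure="full", seed=0)
        ref = GaussianMixture(2, covariance_type="full", random_state=0).fit(X)
        np.testing.assert_allclose(
            np.sort(ours.means.ravel()), np.sort(ref.means_.ravel()), atol=0.05
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((3, 2)), q=2)


class TestPosterior:
    def test_at_component_mean_far_from_other(self):
        m = fit_gmm(two_bump_data(seed=8)[0], q=2, structure="full", seed=0)
        k = int(np.argmin(m.means.ravel()))
        p = posterior(m, m.means[k])
        assert p[k] > 0.999

    def test_symmetric_midpoint(self):
        model = GmmModel(
            q=2, structure="full",
            means=np.array([[0.0], [4.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            weights=np.array([0.5, 0.5]),
            feature_names=("f0",),
        )
        np.testing.assert_allclose(posterior(model, np.array([2.0])), [0.5, 0.5])

    def test_matches_naive_density_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 2)) + rng.choice([0, 6], size=(300, 1))
        m = fit_gmm(X, q=2, structure="full", seed=1)
        for _ in range(20):
            v = rng.normal(0, 4, size=2)
            np.testing.assert_allclose(
                posterior(m, v), naive_posterior(m, v), atol=1e-10
            )

    def test_batch_rows_sum_to_one(self):
        m = fit_gmm(two_bump_data(seed=10)[0], q=2, seed=0)
        V = np.linspace(-3, 13, 50)[:, None]
        P = posterior(m, V)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)


class TestBic:
    def test_free_parameter_counts(self):
        base = dict(means=np.zeros((3, 2)), weights=np.full(3, 1 / 3),
                    feature_names=("a", "b"))
        full = GmmModel(q=3, structure="full", covariances=np.zeros((3, 2, 2)), **base)
        assert full.n_parameters() == 3 * 2 + 3 * 3 + 2  # qD + qD(D+1)/2 + (q-1)
        diag = GmmModel(q=3, structure="diag", covariances=np.zeros((3, 2)), **base)
        assert diag.n_parameters() == 6 + 6 + 2
        sph = GmmModel(q=3, structure="spherical", covariances=np.zeros(3), **base)
        assert sph.n_parameters() == 6 + 3 + 2
        tied = GmmModel(q=3, structure="tied", covariances=np.zeros((2, 2)), **base)
        assert tied.n_parameters() == 6 + 3 + 2

    def test_search_prefers_true_component_count(self):
        X, _ = two_bump_data(seed=11, n=600)
        records = bic_model_search(
            {("f0",): X}, q_range=(1, 2, 3, 4, 5), structures=("full",), seed=0
        )
        assert records[0].q == 2

    def test_failed_fits_recorded_not_ranked(self):
        X = np.random.default_rng(0).normal(size=(8, 1))
        records = bic_model_search(
            {("f0",): X}, q_range=(2, 30), structures=("full",), seed=0
        )
        failed = [r for r in records if r.error is not None]
        assert len(failed) == 1 and failed[0].q == 30
        assert records[0].q == 2


class TestLabeling:
    def cal(self):
        C = np.array([[1.0, 0.3, 1.0], [4.0, 0.85, 60.0], [4.4, 0.95, 280.0]])
        return CalibrationMatrix(
            C=C, ci_low=C, ci_high=C,
            class_names=("sand", "gravel", "boulders"),
            feature_names=("E", "H_prime", "var_G"), B=100,
        )

    def test_two_components_map_to_end_members(self):
        m = GmmModel(q=2, structure="full",
                     means=np.array([[2.5], [1.0]]),  # deliberately unsorted
                     covariances=np.array([[[0.1]], [[0.1]]]),
                     weights=np.array([0.5, 0.5]), feature_names=("E",))
        assert label_components(m, self.cal()) == ("boulders", "sand")

    def test_four_components_middle_two_are_gravel(self):
        m = GmmModel(q=4, structure="full",
                     means=np.array([[30.0, 0.8], [1.0, 0.3], [280.0, 0.95], [120.0, 0.9]]),
                     covariances=np.tile(np.eye(2), (4, 1, 1)),
                     weights=np.full(4, 0.25), feature_names=("var_G", "H_prime"))
        labels = label_components(m, self.cal())
        assert sorted(labels) == ["boulders", "gravel", "gravel", "sand"]
        assert labels[1] == "sand" and labels[2] == "boulders"

    def test_three_components_nearest_signature_identity(self):
        cal = self.cal()
        m = GmmModel(q=3, structure="full",
                     means=cal.C.copy(),
                     covariances=np.tile(np.eye(3), (3, 1, 1)),
                     weights=np.full(3, 1 / 3),
                     feature_names=("E", "H_prime", "var_G"))
        assert label_components(m, cal) == ("sand", "gravel", "boulders")

    def test_interpolated_means_for_gravel_split(self):
        cal = self.cal()
        mu = interpolated_means(cal, ("var_G", "H_prime"), 4)
        np.testing.assert_allclose(mu[1], [(1 + 60) / 2, (0.3 + 0.85) / 2])
        np.testing.assert_allclose(mu[2], [(60 + 280) / 2, (0.85 + 0.95) / 2])
        assert interpolated_means(cal, ("E",), 2).shape == (2, 1)


class TestClassifyGmm:
    def fitted_model(self, scene_texture, calibration, q, features):
        _, _, tex = scene_texture
        X, _ = tex.feature_matrix(features)
        m = fit_gmm(
            X, q=q, init="means",
            init_means=interpolated_means(calibration, features, q),
            feature_names=features,
        )
        m.component_labels = label_components(m, calibration)
        return tex, m

    def test_zero_threshold_never_emits_other(self, scene_texture, calibration):
        tex, m = self.fitted_model(scene_texture, calibration, 2, ("E",))
        cmap, _ = classify_gmm(tex, m, acceptance_threshold=0.0)
        from sonartex.maps import NULL

        assert not (cmap.labels == NULL).any()

    def test_threshold_rejects_uncertain_window(self):
        model = GmmModel(
            q=2, structure="full",
            means=np.array([[0.0], [2.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            weights=np.array([0.5, 0.5]),
            feature_names=("E",),
            component_labels=("sand", "boulders"),
        )
        # a point with posteriors (0.55, 0.45) must fall below a 0.6 threshold
        v = np.array([0.9])
        p = posterior(model, v)
        assert 0.5 < p.max() < 0.6

    def test_posterior_map_substrates_sum_to_one(self, scene_texture, calibration):
        tex, m = self.fitted_model(
            scene_texture, calibration, 4, ("var_G", "H_prime")
        )
        cmap, pmap = classify_gmm(tex, m, acceptance_threshold=0.0)
        maps = pmap.substrate_maps()
        total = sum(maps.values())
        defined = ~np.isnan(total)
        np.testing.assert_allclose(total[defined], 1.0)
        # the two gravel components are reported as one gravel class
        assert set(maps) == {"sand", "gravel", "boulders"}
        assert m.component_labels.count("gravel") == 2
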