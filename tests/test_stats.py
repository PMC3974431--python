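"""PCA, rank-safe LDA, posteriors, cross-validation and hit ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from wingmorph import (
    ConfusionMatrix,
    classify,
    gpa,
    hit_ratios,
    lda_fit,
    loo_crossvalidate,
    mahalanobis_to_groups,
    pca_fit,
    posterior_probabilities,
    project_to_tangent,
)


def two_group_1d(rng, n=20, mu=10.0, sd=0.1):
    x = np.concatenate([rng.normal(0, sd, n), rng.normal(mu, sd, n)])[:, None]
    y = np.array(["a"] * n + ["b"] * n)
    return x, y


class TestPCA:
    def test_percent_variance_sums_to_100(self, rng):
        model = pca_fit(rng.normal(size=(30, 5)))
        assert model.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_collinear_data_has_one_axis_of_variance(self, rng):
        t = rng.normal(size=40)
        x = np.outer(t, [1.0, 2.0, -1.0]) + [5, 5, 5]
        model = pca_fit(x)
        assert model.percent_variance[0] == pytest.approx(100.0, abs=1e-9)
        assert np.all(model.percent_variance[1:] < 1e-9)

    def test_axes_orthonormal(self, rng):
        model = pca_fit(rng.normal(size=(25, 6)))
        np.testing.assert_allclose(model.axes @ model.axes.T, np.eye(model.n_components), atol=1e-9)

    def test_full_rank_scores_preserve_pairwise_distances(self, rng):
        x = rng.normal(size=(15, 4))
        model = pca_fit(x)
        np.testing.assert_allclose(pdist(model.scores), pdist(x - x.mean(axis=0)), atol=1e-9)


class TestLDAFit:
    def test_separated_groups_classified_perfectly(self, rng):
        x, y = two_group_1d(rng)
        model = lda_fit(x, y)
        assert model.discriminant_axes.shape[1] == 1
        pred, _ = classify(model, model.transform(x))
        assert np.all(pred == y)

    def test_axis_count_bounded_by_groups(self, rng):
        x = rng.normal(size=(40, 6))
        y = np.repeat(["a", "b", "c", "d"], 10)
        model = lda_fit(x, y)
        assert model.discriminant_axes.shape[1] <= 3

    def test_small_group_named_in_error(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="'b'"):
            lda_fit(x, ["a", "a", "a", "a", "b"])

    def test_rank_deficient_input_needs_reduction(self, three_group_dataset):
        """Raw tangent coordinates (rank 2k-4) break LDA unless PCs are retained."""
        _, ds = three_group_dataset
        scores = project_to_tangent(gpa(ds)).matrix
        labels = list(ds.labels())
        with pytest.raises(ValueError, match="singular|positive-definite"):
            lda_fit(scores, labels, n_components=scores.shape[1])
        model = lda_fit(scores, labels, n_components="auto")
        assert model.n_components <= 2 * ds.k - 4

    def test_priors_resolution(self, rng):
        x, y = two_group_1d(rng, n=10)
        x2, y2 = two_group_1d(rng, n=30)
        model = lda_fit(np.vstack([x[:10], x2[30:]]), ["a"] * 10 + ["b"] * 30)
        np.testing.assert_allclose(model.priors, [0.25, 0.75])
        model_eq = lda_fit(np.vstack([x[:10], x2[30:]]), ["a"] * 10 + ["b"] * 30, priors="equal")
        np.testing.assert_allclose(model_eq.priors, [0.5, 0.5])
        with pytest.raises(ValueError, match="priors"):
            lda_fit(x, y, priors="weird")


class TestMahalanobisAndPosteriors:
    @pytest.fixture()
    def toy_model(self, rng):
        # 2-D, two groups, near-identity pooled covariance
        x = np.vstack([rng.normal(0, 1.0, size=(200, 2)), rng.normal(0, 1.0, size=(200, 2)) + [8, 0]])
        y = np.array(["g1"] * 200 + ["g2"] * 200)
        return lda_fit(x, y, n_components=2)

    def test_zero_at_group_mean(self, toy_model):
        md = mahalanobis_to_groups(toy_model, toy_model.group_means[0])
        assert md[0] == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_diagonal_covariance(self):
        from wingmorph.stats import LDAModel, PCAModel

        pca = PCAModel(
            mean_row=np.zeros(2), axes=np.eye(2), eigenvalues=np.ones(2),
            percent_variance=np.array([50.0, 50.0]), scores=np.zeros((1, 2)),
        )
        model = LDAModel(
            groups=("g",), priors=np.array([1.0]), pc_transform=pca,
            group_means=np.zeros((1, 2)), pooled_covariance=np.diag([1.0, 4.0]),
            discriminant_axes=np.eye(2),
        )
        md = mahalanobis_to_groups(model, np.array([1.0, 2.0]))
        assert md[0] == pytest.approx(np.sqrt(2.0), abs=1e-12)  # 1/1 + 4/4 = 2

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        from wingmorph.stats import LDAModel, PCAModel

        means = rng.normal(size=(3, 4))
        pca = PCAModel(
            mean_row=np.zeros(4), axes=np.eye(4), eigenvalues=np.ones(4),
            percent_variance=np.full(4, 25.0), scores=np.zeros((1, 4)),
        )
        model = LDAModel(
            groups=("a", "b", "c"), priors=np.full(3, 1 / 3), pc_transform=pca,
            group_means=means, pooled_covariance=np.eye(4), discriminant_axes=np.eye(4)[:, :2],
        )
        row = rng.normal(size=4)
        np.testing.assert_allclose(
            mahalanobis_to_groups(model, row), np.linalg.norm(means - row, axis=1), atol=1e-12
        )

    def test_posteriors_sum_to_one_even_far_away(self, toy_model):
        pp = posterior_probabilities(toy_model, np.array([1e4, -1e4]))
        assert pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(pp >= 0)

    def test_symmetric_point_splits_evenly(self, rng):
        x = np.vstack([rng.normal(0, 1.0, size=(500, 1)), rng.normal(2.0, 1.0, size=(500, 1))])
        y = np.array(["a"] * 500 + ["b"] * 500)
        model = lda_fit(x, y, priors="equal", n_components=1)
        mid = model.group_means.mean(axis=0)
        pp = posterior_probabilities(model, mid)
        np.testing.assert_allclose(pp, [0.5, 0.5], atol=1e-9)

    def test_closed_form_two_group_ratio(self):
        """Means 0 and 2, unit variance, row at 0: PP_a = e^2 / (1 + e^2)."""
        from wingmorph.stats import LDAModel, PCAModel

        pca = PCAModel(
            mean_row=np.zeros(1), axes=np.eye(1), eigenvalues=np.ones(1),
            percent_variance=np.array([100.0]), scores=np.zeros((1, 1)),
        )
        model = LDAModel(
            groups=("a", "b"), priors=np.array([0.5, 0.5]), pc_transform=pca,
            group_means=np.array([[0.0], [2.0]]), pooled_covariance=np.eye(1),
            discriminant_axes=np.eye(1),
        )
        pp = posterior_probabilities(model, np.array([0.0]))
        e2 = np.exp(2.0)
        assert pp[0] == pytest.approx(e2 / (1 + e2), abs=1e-12)

    def test_equal_priors_argmax_matches_min_md(self, rng):
        x = rng.normal(size=(60, 3)) + np.repeat(rng.normal(scale=3, size=(3, 3)), 20, axis=0)
        y = np.repeat(["a", "b", "c"], 20)
        model = lda_fit(x, y, priors="equal")
        for row in rng.normal(scale=2, size=(20, model.n_components)):
            md = mahalanobis_to_groups(model, row)
            pp = posterior_probabilities(model, row)
            assert np.argmin(md) == np.argmax(pp)

    def test_dimension_mismatch(self, toy_model):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_to_groups(toy_model, np.zeros(5))

    def test_whitening_invariance(self, rng):
        """Posteriors unchanged when rows and model see the same affine map."""
        x = rng.normal(size=(90, 4)) + np.repeat(rng.normal(scale=4, size=(3, 4)), 30, axis=0)
        y = np.repeat(["a", "b", "c"], 30)
        a = rng.normal(size=(4, 4)) + 3 * np.eye(4)  # well-conditioned invertible map
        b = rng.normal(size=4)
        m0 = lda_fit(x, y, n_components=4)
        m1 = lda_fit(x @ a + b, y, n_components=4)
        probe = rng.normal(size=(10, 4))
        for row in probe:
            pp0 = posterior_probabilities(m0, m0.transform(row)[0])
            pp1 = posterior_probabilities(m1, m1.transform(row @ a + b)[0])
            np.testing.assert_allclose(pp0, pp1, atol=1e-8)


class TestTies:
    def test_exact_tie_goes_to_first_group_and_flags(self):
        from wingmorph.stats import LDAModel, PCAModel

        pca = PCAModel(
            mean_row=np.zeros(1), axes=np.eye(1), eigenvalues=np.ones(1),
            percent_variance=np.array([100.0]), scores=np.zeros((1, 1)),
        )
        model = LDAModel(
            groups=("a", "b"), priors=np.array([0.5, 0.5]), pc_transform=pca,
            group_means=np.array([[-1.0], [1.0]]), pooled_covariance=np.eye(1),
            discriminant_axes=np.eye(1),
        )
        labels, ties = classify(model, np.array([[0.0]]))
        assert labels[0] == "a" and ties[0]


class TestCrossValidation:
    def test_separable_groups_hit_100(self, rng):
        x, y = two_group_1d(rng, n=15)
        conf = loo_crossvalidate(x, y)
        assert hit_ratios(conf).overall == 100.0
        assert conf.n_misclassified == 0

    def test_row_sums_equal_group_sizes(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.repeat(["a", "b", "c", "d"], 10)
        conf = loo_crossvalidate(x, y)
        np.testing.assert_array_equal(conf.counts.sum(axis=1), [10, 10, 10, 10])

    def test_permuted_labels_score_at_chance(self, rng):
        """Pure noise in 4 equal groups: LOO accuracy within 5 points of 25%."""
        x = rng.normal(size=(200, 4))
        y = rng.permutation(np.repeat(["a", "b", "c", "d"], 50))
        conf = loo_crossvalidate(x, y)
        assert abs(conf.overall_hit_ratio - 25.0) <= 5.0


class TestHitRatios:
    def test_identity_counts_all_100(self):
        conf = ConfusionMatrix(groups=("a", "b"), counts=np.diag([4, 6]))
        hr = hit_ratios(conf)
        assert hr.per_group_display == {"a": 100, "b": 100}
        assert hr.overall == 100.0 and hr.n_misclassified == 0

    def test_rounding_display_vs_internal(self):
        conf = ConfusionMatrix(groups=("a", "b"), counts=np.array([[10, 1], [0, 5]]))
        hr = hit_ratios(conf)
        assert hr.per_group[("a")] == pytest.approx(100 * 10 / 11)
        assert hr.per_group_display["a"] == 91
        assert hr.overall == pytest.approx(round(100 * 15 / 16, 2))

    def test_empty_row_flagged(self):
        conf = ConfusionMatrix(groups=("a", "b"), counts=np.array([[3, 0], [0, 0]]))
        hr = hit_ratios(conf)
        assert hr.empty_groups == ("b",)
        assert "b" not in hr.per_group


class TestSklearnCrossCheck:
    """Independent reference implementation agrees on predicted labels."""

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_predictions_match_reference_lda(self, seed):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        r = np.random.default_rng(seed)
        n_per, p = int(r.integers(10, 34)), int(r.integers(2, 6))
        centers = r.normal(scale=3.0, size=(3, p))
        x = np.vstack([r.normal(size=(n_per, p)) + c for c in centers])
        y = np.repeat(["a", "b", "c"], n_per)
        ours = lda_fit(x, y, priors="equal", n_components=p)
        pred_ours, _ = classify(ours, ours.transform(x))
        ref = sklearn.LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(x, y)
        assert np.all(pred_ours == ref.predict(x))
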