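"""CVA, classification accuracy, external projection, membership probabilities."""

import numpy as np
import pytest
from scipy.linalg import eigh, subspace_angles

from vertmorph import (
    choose_n_pcs,
    classify,
    fit_cva,
    fit_pca,
    membership_probabilities,
    project_external,
)


def two_cluster_scores(rng, n_per=10, sep=10.0, dims=2):
    a = rng.standard_normal((n_per, dims))
    b = rng.standard_normal((n_per, dims))
    b[:, 0] += sep
    scores = np.vstack([a, b])
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    return scores, labels


class TestFitCva:
    def test_separated_clusters_classified_perfectly(self, rng):
        scores, labels = two_cluster_scores(rng)
        report = classify(scores, labels, mode="resubstitution")
        assert report.accuracy == 1.0

    def test_whitening_of_training_scores(self, rng):
        scores = rng.standard_normal((30, 5))
        labels = np.array(["a", "b", "c"] * 10)
        model = fit_cva(scores, labels)
        levels = model.group_labels
        n, g = len(scores), len(levels)
        pooled = np.zeros((model.n_canonical, model.n_canonical))
        for lv in levels:
            sub = model.training_cv[labels == lv]
            dev = sub - sub.mean(axis=0)
            pooled += dev.T @ dev
        pooled /= n - g
        assert np.allclose(pooled, np.eye(model.n_canonical), atol=1e-6)

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        scores = rng.standard_normal((18, 4))
        labels = np.array(["a", "b", "c"] * 6)
        model = fit_cva(scores, labels)
        # oracle: scipy's generalized eigensolver on (B, W) built directly
        grand = scores.mean(axis=0)
        W = np.zeros((4, 4))
        B = np.zeros((4, 4))
        for lv in set(labels.tolist()):
            sub = scores[labels == lv]
            dev = sub - sub.mean(axis=0)
            W += dev.T @ dev
            d = sub.mean(axis=0) - grand
            B += len(sub) * np.outer(d, d)
        W /= len(scores) - 3
        B /= 2
        vals, vecs = eigh(B, W)
        oracle = vecs[:, np.argsort(vals)[::-1][: model.n_canonical]]
        angles = subspace_angles(model.canonical_vectors, oracle)
        assert angles.max() < 1e-6

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for rep in range(30):
            scores, labels = two_cluster_scores(rng, n_per=12, sep=0.0)
            accs.append(classify(scores, labels, mode="resubstitution").accuracy)
        # chance level 1/2; resubstitution optimism keeps it slightly above
        assert 0.4 < np.mean(accs) < 0.75

    def test_too_many_pcs_rejected(self, rng):
        scores = rng.standard_normal((10, 9))
        labels = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="lower k"):
            fit_cva(scores, labels)

    def test_loo_not_better_than_resubstitution_on_average(self, rng):
        diffs = []
        for rep in range(40):
            scores, labels = two_cluster_scores(rng, n_per=8, sep=1.5, dims=3)
            loo = classify(scores, labels, mode="leave-one-out").accuracy
            resub = classify(scores, labels, mode="resubstitution").accuracy
            diffs.append(resub - loo)
        assert np.mean(diffs) >= 0.0


class TestChooseNPcs:
    def test_cumvar_rule_and_cap(self, lf_space):
        k = choose_n_pcs(lf_space, n_groups=3)
        n = lf_space.scores.shape[0]
        assert 1 <= k <= n - 3 - 1
        if k < n - 4:
            assert lf_space.cumulative_variance()[k - 1] >= 0.95


class TestProjectExternal:
    def test_training_specimen_roundtrip(self, lf_block, lf_space):
        labels = np.array((["a", "b", "c"] * lf_block.n_specimens)[: lf_block.n_specimens])
        k = 5
        model = fit_cva(lf_space.scores[:, :k], labels)
        cv = project_external(model, lf_space, lf_block.consensus, lf_block.aligned[4])
        assert np.allclose(cv, model.training_cv[4], atol=1e-6)

    def test_consensus_maps_to_zero_pc_vector(self, lf_block, lf_space):
        from vertmorph import project

        labels = np.array((["a", "b", "c"] * lf_block.n_specimens)[: lf_block.n_specimens])
        model = fit_cva(lf_space.scores[:, :4], labels)
        # at its own scale the mean shape scores exactly zero
        pc = project(lf_space, lf_block.consensus, check=False)
        assert np.allclose(model.transform(pc[:4]), model.transform(np.zeros(4)),
                           atol=1e-9)
        # through the fossil pathway it is rescaled to unit centroid size,
        # which leaves only a small radial (tangent-approximation) offset
        cv = project_external(model, lf_space, lf_block.consensus, lf_block.consensus)
        assert np.linalg.norm(cv - model.transform(np.zeros(4))) < 0.01

    def test_landmark_mismatch_rejected(self, lf_block, lf_space, rng):
        labels = np.array((["a", "b", "c"] * lf_block.n_specimens)[: lf_block.n_specimens])
        model = fit_cva(lf_space.scores[:, :4], labels)
        with pytest.raises(ValueError, match="mismatch"):
            project_external(model, lf_space, lf_block.consensus,
                             rng.standard_normal((20, 3)))


class TestMembershipProbabilities:
    @staticmethod
    def _toy_model(means):
        means = np.asarray(means, dtype=float)
        g, r = means.shape
        from vertmorph.eco_classify import CVAModel

        return CVAModel(
            canonical_vectors=np.eye(r),
            group_means_cv=means,
            group_labels=[f"g{i}" for i in range(g)],
            pooled_within_cov=np.eye(r),
            mean_scores=np.zeros(r),
            eigenvalues=np.ones(r),
        )

    def test_point_at_group_mean_two_groups(self):
        # other group's mean at d^2 = 8: posterior 1/(1+e^-4) = 0.98201...
        model = self._toy_model([[0.0, 0.0], [np.sqrt(8.0), 0.0]])
        pred = membership_probabilities(model, np.zeros(2))
        assert pred.predicted == "g0"
        assert pred.probability[0] == pytest.approx(1 / (1 + np.exp(-4)), abs=1e-9)
        assert pred.probability[1] == pytest.approx(1 - 1 / (1 + np.exp(-4)), abs=1e-9)

    def test_equidistant_point_uniform(self):
        model = self._toy_model([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        pred = membership_probabilities(model, np.zeros(2))
        assert np.allclose(pred.probability, 0.25, atol=1e-12)

    def test_probabilities_sum_to_one_and_shift_invariant(self, rng):
        for _ in range(20):
            means = rng.standard_normal((4, 3))
            model = self._toy_model(means)
            point = rng.standard_normal(3)
            pred = membership_probabilities(model, point)
            assert pred.probability.sum() == pytest.approx(1.0, abs=1e-9)
            # shifting all means rigidly with the point leaves d^2 differences,
            # hence the posterior, unchanged
            shift = rng.standard_normal(3)
            moved = membership_probabilities(self._toy_model(means + shift), point + shift)
            assert np.allclose(moved.probability, pred.probability, atol=1e-9)

    def test_typicality_at_mean_is_one(self):
        model = self._toy_model([[0.0, 0.0], [5.0, 0.0]])
        pred = membership_probabilities(model, np.zeros(2))
        assert pred.typicality[0] == pytest.approx(1.0)
        assert pred.typicality[1] < 1e-4
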