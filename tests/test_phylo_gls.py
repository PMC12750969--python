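"""Tree input, Brownian covariance, and PGLS behaviour."""

import numpy as np
import pytest

from vertmorph import bm_covariance, pgls_fit, read_newick, simulate_tree


@pytest.fixture()
def three_taxon_tree(tmp_path):
    path = tmp_path / "tree.nwk"
    path.write_text("((A:1,B:1):1,C:2);\n")
    return read_newick(path)


class TestReadNewick:
    def test_parses_tips_and_depths(self, three_taxon_tree):
        assert sorted(three_taxon_tree.taxa) == ["A", "B", "C"]
        depths = three_taxon_tree.depths()
        assert all(d == pytest.approx(2.0) for d in depths.values())

    def test_duplicate_tip_rejected(self, tmp_path):
        path = tmp_path / "dup.nwk"
        path.write_text("((A:1,A:1):1,C:2);\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_newick(path)

    def test_missing_branch_length_rejected(self, tmp_path):
        path = tmp_path / "nolen.nwk"
        path.write_text("((A:1,B),C:2);\n")
        with pytest.raises(ValueError, match="branch length"):
            read_newick(path)

    def test_prune_path_length(self, three_taxon_tree):
        pruned = three_taxon_tree.prune(["A", "C"])
        assert sorted(pruned.taxa) == ["A", "C"]
        pdm = pruned.tree.phylogenetic_distance_matrix()
        (a, c) = sorted(
            (leaf.taxon for leaf in pruned.tree.leaf_node_iter()),
            key=lambda t: t.label,
        )
        assert pdm.patristic_distance(a, c) == pytest.approx(4.0)

    def test_prune_missing_species_error(self, three_taxon_tree):
        with pytest.raises(KeyError, match="Z"):
            three_taxon_tree.prune(["A", "Z"])


class TestBmCovariance:
    def test_star_tree_identity(self, tmp_path):
        path = tmp_path / "star.nwk"
        path.write_text("(A:1,B:1,C:1,D:1);\n")
        cov = bm_covariance(read_newick(path), ["A", "B", "C", "D"])
        assert np.allclose(cov, np.eye(4), atol=1e-12)

    def test_analytic_three_taxon(self, three_taxon_tree):
        cov = bm_covariance(three_taxon_tree, ["A", "B", "C"])
        assert np.allclose(cov, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12)

    def test_random_tree_psd(self):
        for seed in range(5):
            tree = simulate_tree(15, seed=seed)
            cov = bm_covariance(tree, tree.taxa)
            assert np.allclose(cov, cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(cov).min() >= -1e-9

    def test_species_not_in_tree(self, three_taxon_tree):
        with pytest.raises(KeyError, match="Z"):
            bm_covariance(three_taxon_tree, ["A", "Z"])


def ols_anova_oracle(Y, labels):
    """Multivariate one-way ANOVA SS decomposition by direct group means."""
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(labels)
    grand = Y.mean(axis=0)
    ss_total = np.sum((Y - grand) ** 2)
    ss_resid = 0.0
    for lv in set(labels.tolist()):
        sub = Y[labels == lv]
        ss_resid += np.sum((sub - sub.mean(axis=0)) ** 2)
    g = len(set(labels.tolist()))
    n = len(Y)
    ss_effect = ss_total - ss_resid
    f = (ss_effect / (g - 1)) / (ss_resid / (n - g))
    return ss_effect / ss_total, f


class TestPglsFit:
    def test_identity_covariance_equals_ols_anova(self, rng):
        n = 12
        Y = rng.standard_normal((n, 5))
        labels = np.array(["a", "b", "c"] * 4)
        res = pgls_fit(Y, labels, np.eye(n), n_perm=99, seed=0)
        r2, f = ols_anova_oracle(Y, labels)
        assert res.r_squared == pytest.approx(r2, abs=1e-9)
        assert res.F == pytest.approx(f, abs=1e-9)

    def test_invariant_to_covariance_rescaling(self, rng):
        tree = simulate_tree(12, seed=3)
        cov = bm_covariance(tree, tree.taxa)
        Y = rng.standard_normal((12, 4))
        labels = np.array(["a", "b"] * 6)
        res1 = pgls_fit(Y, labels, cov, n_perm=99, seed=5)
        res2 = pgls_fit(Y, labels, 1000.0 * cov, n_perm=99, seed=5)
        assert res1.r_squared == pytest.approx(res2.r_squared, abs=1e-9)
        assert res1.p_value == res2.p_value

    def test_rotation_invariance_of_r_squared(self, rng):
        tree = simulate_tree(10, seed=4)
        cov = bm_covariance(tree, tree.taxa)
        Y = rng.standard_normal((10, 6))
        labels = np.array(["a", "b"] * 5)
        q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        res = pgls_fit(Y, labels, cov, n_perm=99, seed=1)
        rot = pgls_fit(Y @ q, labels, cov, n_perm=99, seed=1)
        assert rot.r_squared == pytest.approx(res.r_squared, abs=1e-9)

    def test_continuity_toward_identity(self, rng):
        # blending C toward I converges on the non-phylogenetic fit
        tree = simulate_tree(14, seed=6)
        cov = bm_covariance(tree, tree.taxa)
        cov /= np.diag(cov).mean()
        Y = rng.standard_normal((14, 4))
        labels = np.array(["a", "b"] * 7)
        r2_ident = pgls_fit(Y, labels, np.eye(14), n_perm=99, seed=0).r_squared
        gaps = []
        for lam in (0.5, 0.1, 0.01):
            blended = lam * cov + (1 - lam) * np.eye(14)
            gaps.append(
                abs(pgls_fit(Y, labels, blended, n_perm=99, seed=0).r_squared - r2_ident)
            )
        assert gaps[-1] < 1e-3
        assert gaps == sorted(gaps, reverse=True)

    def test_effect_size_monotone_in_signal(self, rng):
        from scipy.stats import spearmanr

        tree = simulate_tree(20, seed=9)
        cov = bm_covariance(tree, tree.taxa)
        labels = np.array(["a", "b"] * 10)
        direction = rng.standard_normal(5)
        noise = rng.standard_normal((20, 5))
        grid = np.linspace(0.0, 5.0, 8)
        r2 = []
        for effect in grid:
            Y = noise + np.outer((labels == "a").astype(float), effect * direction)
            r2.append(pgls_fit(Y, labels, cov, n_perm=99, seed=0).r_squared)
        rho = spearmanr(grid, r2).statistic
        assert rho > 0.95

    def test_continuous_predictor(self, rng):
        n = 10
        x = rng.standard_normal(n)
        Y = np.outer(x, rng.standard_normal(3)) + 0.1 * rng.standard_normal((n, 3))
        res = pgls_fit(Y, x, np.eye(n), n_perm=199, seed=0)
        assert res.r_squared > 0.9
        assert res.p_value < 0.05

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            pgls_fit(rng.standard_normal((8, 3)), ["a"] * 8, np.eye(8))

    def test_reproducible_p_values(self, rng):
        tree = simulate_tree(12, seed=1)
        cov = bm_covariance(tree, tree.taxa)
        Y = rng.standard_normal((12, 4))
        labels = np.array(["a", "b"] * 6)
        p1 = pgls_fit(Y, labels, cov, n_perm=199, seed=11).p_value
        p2 = pgls_fit(Y, labels, cov, n_perm=199, seed=11).p_value
        assert p1 == p2
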