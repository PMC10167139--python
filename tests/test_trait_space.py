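"""Phylogenetically informed PCA, pruning, covariance and orientation."""

import numpy as np
import pandas as pd
import pytest

from rootpsf import PhyloPCA, assign_strategy, orient_axes, phylo_vcv, prune_tree
from rootpsf.exceptions import (
    ExperimentDataError,
    OrientationError,
    SingularCovarianceError,
    TreeMismatchError,
)
from rootpsf.phylo import read_newick, root_to_tip_distances, tip_labels


def random_phylo_instance(n, seed):
    """Random tree + traits for property checks."""
    from rootpsf.simulate import SimulationConfig, simulate_traits, simulate_tree

    rng = np.random.default_rng(seed)
    tree = simulate_tree(n, rng)
    cfg = SimulationConfig(n_species=max(n, 4), trait_noise_sd=0.3, phylo_signal=0.6,
                           seed=seed)
    traits, _ = simulate_traits(tree, cfg, rng)
    return tree, traits


class TestPrune:
    def test_prune_to_all_tips_is_identity(self, balanced_tree):
        before = root_to_tip_distances(balanced_tree)
        pruned = prune_tree(balanced_tree, ["A", "B", "Cc", "Dd"])
        assert root_to_tip_distances(pruned) == before

    def test_prune_to_sister_pair_preserves_depths(self, balanced_tree):
        pruned = prune_tree(balanced_tree, ["A", "B"])
        assert sorted(tip_labels(pruned)) == ["A", "B"]
        # A and B keep their original root-to-tip distance of 2
        assert root_to_tip_distances(pruned) == {"A": 2.0, "B": 2.0}

    def test_prune_across_the_root_sums_collapsed_branches(self, balanced_tree):
        pruned = prune_tree(balanced_tree, ["A", "Cc"])
        assert root_to_tip_distances(pruned) == {"A": 2.0, "Cc": 2.0}

    def test_unknown_species_error_names_them(self, balanced_tree):
        with pytest.raises(TreeMismatchError, match="Zz"):
            prune_tree(balanced_tree, ["A", "Zz"])


class TestVCV:
    def test_star_tree_gives_identity(self):
        star = read_newick("(A:1,B:1,Cc:1);")
        C, labels = phylo_vcv(star)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-12)

    def test_two_tip_tree(self):
        C, labels = phylo_vcv(read_newick("(A:1,B:1);"))
        np.testing.assert_allclose(C, np.eye(2), atol=1e-12)

    def test_shared_path_example(self):
        C, labels = phylo_vcv(read_newick("((A:1,B:1):1,Cc:2);"),
                              order=["A", "B", "Cc"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_zero_branch_lengths_not_positive_definite(self):
        with pytest.raises(SingularCovarianceError):
            phylo_vcv(read_newick("((A:0,B:0):0,Cc:0);"))


class TestPhyloPCA:
    def test_star_phylogeny_matches_ordinary_pca(self, star_traits):
        """With C = I the analysis is an ordinary PCA of the ln-traits."""
        space = PhyloPCA(star_traits, tree=None).fit()

        X = np.log(star_traits.to_numpy())
        Xc = X - X.mean(axis=0)
        S = Xc / Xc.std(axis=0, ddof=1)
        R = np.corrcoef(S, rowvar=False)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        expected_scores = S @ vecs

        got = space.scores.to_numpy()
        for j in range(4):
            col = expected_scores[:, j]
            assert (np.abs(got[:, j] - col).max() < 1e-8
                    or np.abs(got[:, j] + col).max() < 1e-8)
        np.testing.assert_allclose(space.eigenvalues, vals, atol=1e-10)

    def test_cloned_species_get_identical_scores(self, star_traits):
        doubled = pd.concat([star_traits,
                             star_traits.set_index(star_traits.index + "_clone")])
        space = PhyloPCA(doubled).fit()
        for sp in star_traits.index:
            np.testing.assert_allclose(
                space.scores.loc[sp], space.scores.loc[sp + "_clone"], atol=1e-10
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_scores_diagonalize_weighted_covariance(self, seed):
        """S' C^-1 S / (n-1) must be diag(eigenvalues)."""
        tree, traits = random_phylo_instance(8, seed)
        model = PhyloPCA(traits, tree)
        space = model.fit()
        S = space.scores.to_numpy()
        C = model.C
        M = S.T @ np.linalg.solve(C, S) / (len(traits) - 1)
        np.testing.assert_allclose(M, np.diag(space.eigenvalues), atol=1e-8)

    @pytest.mark.parametrize("mode", ["correlation", "covariance"])
    def test_variance_explained_sums_to_100(self, star_traits, mode):
        space = PhyloPCA(star_traits, mode=mode).fit()
        assert space.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
        assert (space.variance_explained >= 0).all()

    def test_translation_of_log_trait_absorbed_by_gls_mean(self, star_traits):
        """Multiplying a trait by a constant (shifting its log) leaves scores unchanged."""
        space1 = PhyloPCA(star_traits).fit()
        shifted = star_traits.copy()
        shifted["SRL"] = shifted["SRL"] * 7.5
        space2 = PhyloPCA(shifted).fit()
        np.testing.assert_allclose(space1.scores, space2.scores, atol=1e-8)

    def test_constant_trait_rejected_in_correlation_mode(self, star_traits):
        bad = star_traits.copy()
        bad["RTD"] = 2.0
        with pytest.raises(ExperimentDataError, match="RTD"):
            PhyloPCA(bad).fit()

    def test_requires_three_species(self, star_traits):
        with pytest.raises(ExperimentDataError):
            PhyloPCA(star_traits.iloc[:2])

    def test_missing_tree_species_is_hard_error(self, star_traits, balanced_tree):
        with pytest.raises(TreeMismatchError):
            PhyloPCA(star_traits, balanced_tree).fit()

    def test_star_fallback_substitutes_identity(self, star_traits, balanced_tree):
        space = PhyloPCA(star_traits, balanced_tree, star_fallback=True).fit()
        reference = PhyloPCA(star_traits).fit()
        np.testing.assert_allclose(space.scores, reference.scores, atol=1e-12)


class TestOrientation:
    def test_oriented_anchor_loadings_positive(self, star_traits):
        space = PhyloPCA(star_traits).fit()
        assert space.loadings.loc["SRL", "collab"] > 0
        assert space.loadings.loc["N", "cons"] > 0

    def test_orientation_idempotent(self, star_traits):
        space = PhyloPCA(star_traits).fit()
        again = orient_axes(space)
        pd.testing.assert_frame_equal(space.scores, again.scores)
        pd.testing.assert_frame_equal(space.loadings, again.loadings)

    def test_reflected_axis_restored(self, star_traits):
        space = PhyloPCA(star_traits).fit()
        flipped = orient_axes(space)
        flipped.scores["collab"] *= -1
        flipped.loadings["collab"] *= -1
        restored = orient_axes(flipped)
        np.testing.assert_allclose(restored.scores, space.scores, atol=1e-12)

    def test_zero_anchor_loading_is_ambiguous(self, star_traits):
        space = PhyloPCA(star_traits).fit()
        space.loadings.loc["SRL", "collab"] = 0.0
        with pytest.raises(OrientationError):
            orient_axes(space)

    def test_geometry_invariant_to_reflection(self, star_traits):
        """Distances computed downstream are identical up to coherent signs."""
        from rootpsf import signed_distance

        space = PhyloPCA(star_traits).fit()
        mirrored = orient_axes(space)
        mirrored.scores["cons"] *= -1
        mirrored.loadings["cons"] *= -1
        mirrored = orient_axes(mirrored)  # re-orient flips it back
        a, b = star_traits.index[:2]
        assert signed_distance(space, a, b, "cons") == pytest.approx(
            signed_distance(mirrored, a, b, "cons"), abs=1e-12
        )


class TestStrategy:
    @pytest.mark.parametrize(
        "collab, cons, expected, boundary",
        [
            (-1, -1, "OS", False),
            (1, 1, "DF", False),
            (1, -1, "DS", False),
            (-1, 1, "OF", False),
            (0, 0, "OS", True),
            (0.5, 0, "DS", True),
        ],
    )
    def test_quadrants_and_tie_rule(self, collab, cons, expected, boundary):
        strategy, flagged = assign_strategy(collab, cons)
        assert strategy == expected
        assert flagged is boundary
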