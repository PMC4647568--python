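"""Independent contrasts, squared-change parsimony and the signal test."""

import numpy as np
import pytest

from triturus_axial.phylo import (
    PhyloError,
    contrast_regression,
    pic,
    signal_permutation_test,
    squared_change_statistic,
)
from triturus_axial.simulate import simulate_bm
from triturus_axial.trees import read_newick
from conftest import random_binary_tree


class TestPic:
    def test_two_tip_closed_form(self):
        t = read_newick("(A:1,B:3);")
        c = pic(t, {"A": 5.0, "B": 1.0})
        assert len(c) == 1
        assert abs(c.standardized[0]) == pytest.approx((5 - 1) / np.sqrt(4))

    def test_constant_traits_give_zero_contrasts(self, fixture_tree):
        traits = {tip: 3.3 for tip in fixture_tree.tip_labels()}
        c = pic(fixture_tree, traits)
        np.testing.assert_allclose(c.standardized, 0.0, atol=1e-12)

    def test_contrast_count_is_tips_minus_one(self, fixture_tree):
        traits = dict(zip(fixture_tree.tip_labels(), range(8)))
        assert len(pic(fixture_tree, {k: float(v) for k, v in traits.items()})) == 7

    def test_matches_independent_reference_implementation(self):
        # expected standardized contrasts computed with R ape::pic on the
        # same tree and trait values, frozen here (sorted; signs are
        # convention-dependent only up to sister order, which ape shares)
        t = read_newick("(((A:1.5,B:2):0.7,C:3.2):0.4,(D:1.1,E:0.9):2.6);")
        x = {"A": 4.1, "B": 6.3, "C": 2.2, "D": 9.0, "E": 8.4}
        expected = sorted(
            [-2.138452491882, 1.303412674054, -1.175949464415, 0.424264068712]
        )
        got = sorted(pic(t, x).standardized)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_linearity_in_traits(self, fixture_tree, rng):
        traits = {tip: float(v) for tip, v in
                  zip(fixture_tree.tip_labels(), rng.normal(size=8))}
        scaled = {k: 2.5 * v - 7.0 for k, v in traits.items()}
        c0 = pic(fixture_tree, traits)
        c1 = pic(fixture_tree, scaled)
        np.testing.assert_allclose(c1.raw, 2.5 * c0.raw, rtol=1e-10)
        np.testing.assert_allclose(c1.variance, c0.variance, rtol=1e-12)

    def test_missing_trait_rejected(self, fixture_tree):
        traits = {tip: 1.0 for tip in fixture_tree.tip_labels()[:-1]}
        with pytest.raises(PhyloError, match="missing"):
            pic(fixture_tree, traits)

    def test_polytomy_rejected(self):
        tree = read_newick("(A:1,B:1,C:1);", polytomy="resolve")
        # resolved trees pass; an unresolved polytomy cannot be built via
        # read_newick's default policy at all
        traits = {"A": 1.0, "B": 2.0, "C": 3.0}
        assert len(pic(tree, traits)) == 2


class TestContrastRegression:
    def test_exact_proportionality(self, fixture_tree, rng):
        traits = {tip: float(v) for tip, v in
                  zip(fixture_tree.tip_labels(), rng.normal(size=8))}
        cx = pic(fixture_tree, traits)
        cy = pic(fixture_tree, {k: 2.0 * v for k, v in traits.items()})
        res = contrast_regression(cx, cy)
        assert res.slope == pytest.approx(2.0)
        assert res.p == pytest.approx(0.0)

    def test_slope_recovery_under_brownian_noise(self, rng):
        tree = random_binary_tree(16, rng)
        slopes = []
        for i in range(1000):
            x = simulate_bm(tree, sigma2=1.0, root_state=0.0, seed=10_000 + i)
            noise = simulate_bm(tree, sigma2=0.25, root_state=0.0, seed=60_000 + i)
            y = {k: 1.5 * x[k] + noise[k] for k in x}
            slopes.append(contrast_regression(pic(tree, x), pic(tree, y)).slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 1.5) <= 3 * se

    def test_type_i_error_calibrated(self, rng):
        tree = random_binary_tree(16, rng)
        rejections = 0
        reps = 2000
        for i in range(reps):
            x = simulate_bm(tree, sigma2=1.0, root_state=0.0, seed=i)
            y = simulate_bm(tree, sigma2=1.0, root_state=0.0, seed=100_000 + i)
            if contrast_regression(pic(tree, x), pic(tree, y)).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_mismatched_trees_rejected(self, fixture_tree, rng):
        other = random_binary_tree(8, rng)
        tx = {tip: 1.0 * i for i, tip in enumerate(fixture_tree.tip_labels())}
        ty = {tip: 1.0 * i for i, tip in enumerate(other.tip_labels())}
        with pytest.raises(PhyloError):
            contrast_regression(pic(fixture_tree, tx), pic(other, ty))


class TestSquaredChange:
    def test_two_tip_closed_form(self):
        t = read_newick("(A:1,B:1);")
        stat, states = squared_change_statistic(t, {"A": 0.0, "B": 4.0})
        assert stat == pytest.approx(8.0)
        assert list(states.values())[0] == pytest.approx(2.0)

    def test_star_tree_mean_and_sum_of_squares(self):
        # a 4-tip star: root state is the arithmetic mean, statistic the SS
        from triturus_axial.trees import PhyloTree, TreeNode

        root = TreeNode()
        values = {"a": 1.0, "b": 2.0, "c": 6.0, "d": 7.0}
        for lbl in values:
            root.add_child(TreeNode(lbl, 1.0))
        tree = PhyloTree(root)
        stat, states = squared_change_statistic(tree, values)
        xs = np.array(list(values.values()))
        assert list(states.values())[0] == pytest.approx(xs.mean())
        assert stat == pytest.approx(((xs - xs.mean()) ** 2).sum())

    def test_shift_invariance_and_quadratic_scaling(self, fixture_tree, rng):
        traits = {tip: float(v) for tip, v in
                  zip(fixture_tree.tip_labels(), rng.normal(size=8))}
        base, _ = squared_change_statistic(fixture_tree, traits)
        shifted, _ = squared_change_statistic(
            fixture_tree, {k: v + 11.0 for k, v in traits.items()}
        )
        scaled, _ = squared_change_statistic(
            fixture_tree, {k: 3.0 * v for k, v in traits.items()}
        )
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(9.0 * base, rel=1e-9)

    def test_zero_iff_constant(self, fixture_tree):
        const = {tip: 5.0 for tip in fixture_tree.tip_labels()}
        assert squared_change_statistic(fixture_tree, const)[0] == pytest.approx(0.0)
        varied = dict(const, dobrogicus=6.0)
        assert squared_change_statistic(fixture_tree, varied)[0] > 0

    def test_weighted_variant_divides_by_branch_length(self):
        t = read_newick("(A:2,B:2);")
        stat, _ = squared_change_statistic(t, {"A": 0.0, "B": 4.0}, weighted=True)
        # optimum at the midpoint: 2²/2 + 2²/2 = 4
        assert stat == pytest.approx(4.0)


class TestSignalTest:
    def test_seeded_runs_are_bit_reproducible(self, fixture_tree, trait_vectors):
        a = signal_permutation_test(fixture_tree, trait_vectors["T_n"], 200, seed=3)
        b = signal_permutation_test(fixture_tree, trait_vectors["T_n"], 200, seed=3)
        assert a.p == b.p
        np.testing.assert_array_equal(a.null_statistics, b.null_statistics)
        assert 1 / 201 <= a.p <= 1.0

    def test_constant_trait_gives_p_one_with_warning(self, fixture_tree):
        traits = {tip: 2.0 for tip in fixture_tree.tip_labels()}
        with pytest.warns(UserWarning, match="constant"):
            res = signal_permutation_test(fixture_tree, traits, 99, seed=0)
        assert res.p == 1.0
        assert res.statistic_observed == pytest.approx(0.0)

    def test_ladder_tree_with_ordered_trait_shows_signal(self):
        # perfectly graded trait on a caterpillar tree: strong signal
        newick = "(((((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5):1,G:6):1,H:7);"
        tree = read_newick(newick)
        traits = dict(zip("ABCDEFGH", map(float, range(8))))
        res = signal_permutation_test(tree, traits, iterations=999, seed=1)
        assert res.p <= 0.05

    def test_unit_weight_statistic_ignores_branch_lengths(self, fixture_tree,
                                                          trait_vectors):
        doubled = fixture_tree.copy()
        for node in doubled.postorder():
            if node.length is not None:
                node.length *= 2.0
        a = signal_permutation_test(fixture_tree, trait_vectors["T_var"], 500, seed=9)
        b = signal_permutation_test(doubled, trait_vectors["T_var"], 500, seed=9)
        assert a.p == b.p
        np.testing.assert_allclose(a.null_statistics, b.null_statistics, rtol=1e-9)
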