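import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylotherm import simulate
from phylotherm.errors import ParameterDomainError
from phylotherm.models import EvolModelSpec
from phylotherm.signal import d_statistic, distance_trait_correlation

from conftest import random_tree


class TestDStatistic:
    def test_clumped_four_tip_hand_value(self, balanced_four):
        res = d_statistic(balanced_four, {"A": 1, "B": 1, "C": 0, "D": 0},
                          n_perm=100, n_sim=100, seed=1)
        assert res.d_obs == pytest.approx(1.0)

    def test_alternating_four_tip_hand_value(self, balanced_four):
        res = d_statistic(balanced_four, {"A": 1, "B": 0, "C": 1, "D": 0},
                          n_perm=100, n_sim=100, seed=1)
        assert res.d_obs == pytest.approx(2.0)

    def test_monomorphic_rejected(self, balanced_four):
        with pytest.raises(ParameterDomainError):
            d_statistic(balanced_four, {"A": 1, "B": 1, "C": 1, "D": 1})

    def test_small_n_perm_warns(self, balanced_four):
        with pytest.warns(UserWarning):
            d_statistic(balanced_four, {"A": 1, "B": 1, "C": 0, "D": 0},
                        n_perm=50, n_sim=100, seed=1)

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_complement_invariance(self, seed):
        """Swapping state labels 0 <-> 1 leaves d_obs and D unchanged."""
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 20)
        states = simulate.sim_random_binary(tree, 0.35, seed=seed)
        a = d_statistic(tree, states, n_perm=150, n_sim=150, seed=7)
        b = d_statistic(tree, 1 - states, n_perm=150, n_sim=150, seed=7)
        assert a.d_obs == pytest.approx(b.d_obs)
        assert a.D == pytest.approx(b.D, abs=1e-6)

    def test_add_one_estimator_never_zero(self):
        tree = simulate.sim_yule(50, 1.0, seed=3)
        states = simulate.sim_threshold_binary(tree, 0.3, seed=3)
        res = d_statistic(tree, states, n_perm=1000, n_sim=200, seed=3)
        assert res.p_random >= 1.0 / 1001.0
        assert res.p_brownian > 0.0

    def test_equal_branch_length_variant_differs_on_uneven_tree(self):
        rng = np.random.default_rng(11)
        tree = random_tree(rng, 30, ultrametric=False)
        states = simulate.sim_random_binary(tree, 0.4, seed=11)
        a = d_statistic(tree, states, 200, 200, seed=5)
        b = d_statistic(tree, states, 200, 200, seed=5,
                        equal_branch_lengths=True)
        assert a.d_obs != pytest.approx(b.d_obs)


class TestMantel:
    def test_perfect_correlation(self):
        # tips embedded on a line (zero-length leaf stubs): patristic
        # distance equals |trait difference| exactly, so r = 1
        from phylotherm.tree import Phylogeny
        tree = Phylogeny.from_newick("(A:0,(B:0,(C:0,D:4):2):1);")
        traits = {"A": 0.0, "B": 1.0, "C": 3.0, "D": 7.0}
        res = distance_trait_correlation(tree, traits, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_planted_association_detected(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, 30)
        trait = simulate.sim_trait(
            tree, EvolModelSpec("BM", {"sigma2": 1.0}), seed=21)
        res = distance_trait_correlation(tree, trait, n_perm=999, seed=2)
        assert res.statistic > 0
        assert res.p_value <= 0.05

    def test_shuffled_trait_is_null(self):
        rng = np.random.default_rng(31)
        tree = random_tree(rng, 30)
        stats = []
        for i in range(20):
            vals = dict(zip(tree.tip_labels, rng.permutation(30).astype(float)))
            stats.append(distance_trait_correlation(
                tree, vals, n_perm=49, seed=i).statistic)
        assert abs(np.mean(stats)) < 0.1

    def test_matches_skbio_mantel_statistic(self):
        """Independent cross-check of the pairwise correlation statistic."""
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel
        rng = np.random.default_rng(41)
        tree = random_tree(rng, 15)
        trait = simulate.sim_trait(
            tree, EvolModelSpec("BM", {"sigma2": 1.0}), seed=41)
        res = distance_trait_correlation(tree, trait, n_perm=9, seed=1)
        D, labs = tree.patristic_matrix()
        x = np.array([trait[l] for l in labs])
        A = np.abs(x[:, None] - x[None, :])
        r, _, _ = mantel(DistanceMatrix(D, labs), DistanceMatrix(A, labs),
                         method="pearson", permutations=0)
        assert res.statistic == pytest.approx(r, abs=1e-10)

    def test_constant_trait_rejected(self, balanced_four):
        with pytest.raises(ParameterDomainError):
            distance_trait_correlation(balanced_four,
                                       {t: 1.0 for t in "ABCD"})
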