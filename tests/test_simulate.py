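import numpy as np
import pytest

from phylotherm import simulate
from phylotherm.errors import ParameterDomainError
from phylotherm.models import EvolModelSpec
from phylotherm.tree import Phylogeny


class TestSimYule:
    def test_cherry_is_ultrametric(self):
        t = simulate.sim_yule(2, 1.0, seed=1)
        d = t.depths()[t.tip_ids]
        assert d[0] == pytest.approx(d[1])

    def test_determinism(self):
        a = simulate.sim_yule(20, 1.0, seed=5).to_newick()
        b = simulate.sim_yule(20, 1.0, seed=5).to_newick()
        c = simulate.sim_yule(20, 1.0, seed=6).to_newick()
        assert a == b and a != c

    def test_tip_count_binary_ultrametric(self):
        t = simulate.sim_yule(37, 2.0, seed=2)
        assert t.n_tips == 37 and t.is_binary() and t.is_ultrametric()

    def test_rescale_height(self):
        t = simulate.sim_yule(10, 1.0, seed=3, rescale_height=1.0)
        assert t.height == pytest.approx(1.0)

    def test_exponential_lineage_growth(self):
        """E[#lineages at time t] = 2 e^{lambda t} when starting from a
        root split; checked at t = 2 within 15%."""
        t_star, lam = 2.0, 1.0
        counts = []
        for i in range(500):
            tree = simulate.sim_yule(64, lam, seed=i)
            depth = tree.depths()
            # lineages crossing time t_star: edges spanning it
            n_cross = sum(
                1 for v in range(1, tree.n_nodes)
                if depth[tree.parent[v]] < t_star <= depth[v]
                or (not tree.children[v] and depth[v] < t_star))
            counts.append(min(n_cross, 64))
        expect = 2 * np.exp(lam * t_star)
        assert np.mean(counts) == pytest.approx(expect, rel=0.15)


class TestSimTrait:
    def test_bm_star_variance(self):
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:2" for i in range(200)) + ");")
        vs = []
        for i in range(50):
            x = simulate.sim_trait(star, EvolModelSpec("BM", {"sigma2": 1.0}),
                                   seed=i)
            vs.append(np.var(x.values, ddof=1))
        assert np.mean(vs) == pytest.approx(2.0, rel=0.15)

    def test_jump_count_mean(self):
        tree = simulate.sim_yule(100, 1.0, seed=9)
        L = tree.total_length()
        lam = 0.8
        counts = []
        spec = EvolModelSpec("JN", {"jump_rate": lam, "jump_var": 1.0})
        for i in range(100):
            _, det = simulate.sim_trait(tree, spec, seed=i,
                                        return_details=True)
            counts.append(det["jump_counts"].sum())
        assert np.mean(counts) == pytest.approx(lam * L, rel=0.1)

    def test_degenerate_parameters_give_constant(self):
        tree = simulate.sim_yule(10, 1.0, seed=4)
        x = simulate.sim_trait(tree, EvolModelSpec(
            "BMJN", {"sigma2": 0.0, "jump_rate": 0.0, "jump_var": 1.0}),
            root_state=3.5, seed=1)
        assert np.allclose(x.values, 3.5)

    @pytest.mark.parametrize("family,params", [
        ("OU", {"sigma2": 1.0, "ou_alpha": 0.5}),
        ("EB", {"sigma2": 1.0, "eb_rate": -0.5}),
        ("VG", {"vg_sigma2": 1.0, "vg_nu": 0.5}),
        ("NIG", {"nig_alpha": 2.0, "nig_delta": 1.0}),
        ("BMVG", {"sigma2": 0.5, "vg_sigma2": 0.5, "vg_nu": 0.5}),
    ])
    def test_families_produce_finite_reproducible_traits(self, family,
                                                         params):
        tree = simulate.sim_yule(30, 1.0, seed=8)
        a = simulate.sim_trait(tree, EvolModelSpec(family, params), seed=3)
        b = simulate.sim_trait(tree, EvolModelSpec(family, params), seed=3)
        assert np.isfinite(a.values).all()
        assert np.allclose(a.values, b.values)

    def test_levy_family_variance_matches_unit_variance(self):
        """Tip variance on a tall star tree approximates T * (-psi''(0))."""
        from phylotherm.levy import unit_variance
        star = Phylogeny.from_newick(
            "(" + ",".join(f"t{i}:3" for i in range(400)) + ");")
        for family, params in [
                ("JN", {"jump_rate": 1.0, "jump_var": 2.0}),
                ("VG", {"vg_sigma2": 1.5, "vg_nu": 0.5}),
                ("NIG", {"nig_alpha": 2.0, "nig_delta": 1.0})]:
            vs = [np.var(simulate.sim_trait(
                star, EvolModelSpec(family, params), seed=i).values, ddof=1)
                for i in range(30)]
            assert np.mean(vs) == pytest.approx(
                3.0 * unit_variance(family, params), rel=0.15)


class TestBinaryStates:
    def test_exact_prevalence(self):
        tree = simulate.sim_yule(10, 1.0, seed=1)
        s = simulate.sim_threshold_binary(tree, 0.5, seed=2)
        assert s.sum() == 5
        r = simulate.sim_random_binary(tree, 0.5, seed=2)
        assert r.sum() == 5

    def test_determinism(self):
        tree = simulate.sim_yule(30, 1.0, seed=1)
        a = simulate.sim_threshold_binary(tree, 0.3, seed=9)
        b = simulate.sim_threshold_binary(tree, 0.3, seed=9)
        assert (a == b).all()

    def test_unachievable_prevalence_rejected(self):
        tree = simulate.sim_yule(10, 1.0, seed=1)
        with pytest.raises(ParameterDomainError):
            simulate.sim_threshold_binary(tree, 0.01, seed=1)


class TestProteomePA:
    def test_equal_frequencies_mean_half(self):
        recs = simulate.sim_proteome(100, 300, 0.05, 0.05, seed=7)
        from phylotherm.composition import arg_lys_ratios
        df = arg_lys_ratios({"g": recs})
        # SE of the genome mean ~ sqrt(0.25 / (n_RK per protein)) / sqrt(100)
        se = np.sqrt(0.25 / 30.0) / np.sqrt(100)
        assert abs(df.loc["g", "mean_ratio"] - 0.5) < 3 * se

    def test_zero_arg_frequency(self):
        recs = simulate.sim_proteome(20, 100, 0.0, 0.1, seed=8)
        from phylotherm.composition import arg_lys_ratios
        df = arg_lys_ratios({"g": recs})
        assert df.loc["g", "mean_ratio"] == 0.0

    def test_pa_round_trip_with_clade_scoring(self):
        from phylotherm.composition import clade_specific_families
        tree = simulate.sim_yule(40, 1.0, seed=11)
        clade = tree.tip_labels[:10]
        pa = simulate.sim_pa_matrix(tree, clade, n_families=500,
                                    n_planted=20, seed=11)
        hits = clade_specific_families(pa, clade)
        planted = [i for i in hits.index if i.startswith("planted_")]
        assert len(planted) == 20

    def test_substreams_independent_of_other_stages(self):
        tree = simulate.sim_yule(10, 1.0, seed=21)
        a = simulate.sim_trait(tree, EvolModelSpec("BM", {"sigma2": 1}),
                               seed=21)
        # drawing a proteome with the same master seed must not change the
        # trait stream
        simulate.sim_proteome(5, 50, 0.05, 0.05, seed=21)
        b = simulate.sim_trait(tree, EvolModelSpec("BM", {"sigma2": 1}),
                               seed=21)
        assert np.allclose(a.values, b.values)
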