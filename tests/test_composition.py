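import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylotherm import simulate
from phylotherm.composition import (arg_lys_ratios, clade_specific_families,
                                    find_cold_clades, group_compare,
                                    protein_rk_ratio)
from phylotherm.errors import ParameterDomainError
from phylotherm.tree import Phylogeny

from conftest import random_tree
from oracles import brute_force_cold_clades


class TestArgLysRatios:
    @pytest.mark.parametrize("seq,expected", [
        ("RRKK", 0.5), ("RRRK", 0.75), ("rrkk", 0.5), ("RAAAK", 0.5),
    ])
    def test_per_protein_ratio(self, seq, expected):
        _, _, r = protein_rk_ratio(seq)
        assert r == pytest.approx(expected)

    def test_no_rk_protein_excluded(self):
        df = arg_lys_ratios({"g": [("p1", "AAAA"), ("p2", "RK")]})
        assert df.loc["g", "n_excluded"] == 1
        assert df.loc["g", "mean_ratio"] == pytest.approx(0.5)

    def test_genome_mean_is_mean_of_ratios_not_pooled(self):
        # proteins RK (0.5) and RRRK (0.75): mean 0.625, pooled 4R/6 = 0.667
        df = arg_lys_ratios({"g": [("p1", "RK"), ("p2", "RRRK")]})
        assert df.loc["g", "mean_ratio"] == pytest.approx(0.625)
        assert df.loc["g", "pooled_ratio"] == pytest.approx(4 / 6)
        pooled = arg_lys_ratios({"g": [("p1", "RK"), ("p2", "RRRK")]},
                                pooled=True)
        assert pooled.loc["g", "ratio"] == pytest.approx(4 / 6)

    def test_duplicating_protein_set_preserves_mean(self):
        prots = [("p1", "RKKK"), ("p2", "RRKK"), ("p3", "RRRRK")]
        a = arg_lys_ratios({"g": prots}).loc["g", "mean_ratio"]
        b = arg_lys_ratios({"g": prots + prots}).loc["g", "mean_ratio"]
        assert a == pytest.approx(b)

    def test_nucleotide_sequence_warns(self):
        with pytest.warns(UserWarning, match="nucleotide"):
            arg_lys_ratios({"g": [("p1", "ACGTACGTACGTACGTACGT")]})

    def test_reads_fasta_files(self, tmp_path):
        recs = simulate.sim_proteome(10, 50, 0.1, 0.1, seed=1,
                                     genome_id="gX")
        path = tmp_path / "gX.faa"
        simulate.write_fasta(recs, path)
        df = arg_lys_ratios([str(path)])
        assert list(df.index) == ["gX"]
        assert df.loc["gX", "n_proteins"] == 10


class TestFindColdClades:
    def test_planted_clade_and_singleton(self):
        nwk = "(((c1:1,c2:1):1,(c3:1,c4:1):1):1,((w1:1,w2:1):1,(w3:1,c5:1):1):1);"
        tree = Phylogeny.from_newick(nwk)
        flags = {t: t.startswith("c") for t in tree.tip_labels}
        clades = find_cold_clades(tree, flags, min_size=2)
        assert len(clades) == 1 and sorted(clades[0].tips) == \
            ["c1", "c2", "c3", "c4"]
        with_singletons = find_cold_clades(tree, flags, min_size=1)
        assert {frozenset(c.tips) for c in with_singletons} == \
            {frozenset(["c1", "c2", "c3", "c4"]), frozenset(["c5"])}

    def test_all_cold_returns_whole_tree(self, balanced_four):
        clades = find_cold_clades(balanced_four,
                                  {t: True for t in "ABCD"})
        assert len(clades) == 1 and clades[0].size == 4

    def test_no_cold_tips_empty(self, balanced_four):
        assert find_cold_clades(balanced_four,
                                {t: False for t in "ABCD"}) == []

    def test_unclassified_breaks_exclusivity_unless_ignored(self):
        tree = Phylogeny.from_newick("((c1:1,u1:1):1,(c2:1,w1:1):1);")
        flags = {"c1": True, "c2": True, "u1": None, "w1": False}
        assert find_cold_clades(tree, flags, min_size=2) == []
        ignored = find_cold_clades(tree, flags, min_size=1,
                                   ignore_unclassified=True)
        assert any("c1" in c.tips for c in ignored)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10 ** 6), st.integers(10, 100),
           st.floats(0.1, 0.6))
    def test_matches_exhaustive_enumeration(self, seed, n, prev):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, n)
        flags = {t: bool(rng.random() < prev) for t in tree.tip_labels}
        if not any(flags.values()):
            flags[tree.tip_labels[0]] = True
        for min_size in (1, 2, 4):
            got = {frozenset(c.tips)
                   for c in find_cold_clades(tree, flags, min_size=min_size)}
            want = set(brute_force_cold_clades(tree, flags, min_size))
            assert got == want

    def test_output_clades_disjoint(self):
        rng = np.random.default_rng(99)
        tree = random_tree(rng, 60)
        flags = {t: bool(rng.random() < 0.5) for t in tree.tip_labels}
        clades = find_cold_clades(tree, flags, min_size=1)
        seen = set()
        for c in clades:
            assert not (seen & set(c.tips))
            seen |= set(c.tips)


class TestCladeSpecificFamilies:
    def _matrix(self):
        tree = simulate.sim_yule(30, 1.0, seed=5)
        clade = tree.tip_labels[:8]
        pa = simulate.sim_pa_matrix(tree, clade, n_families=300,
                                    background_p=0.5, n_planted=10, seed=5)
        return pa, clade

    def test_perfect_marker_scores_one(self):
        pa = pd.DataFrame({"g1": [1, 1], "g2": [1, 1], "g3": [0, 1]},
                          index=["famA", "famB"])
        hits = clade_specific_families(pa, ["g1", "g2"], in_min=1.0,
                                       out_max=0.0)
        assert list(hits.index) == ["famA"]
        assert hits.loc["famA", "score"] == pytest.approx(1.0)

    def test_ubiquitous_family_not_reported(self):
        pa = pd.DataFrame({"g1": [1], "g2": [1], "g3": [1]}, index=["famA"])
        assert len(clade_specific_families(pa, ["g1", "g2"])) == 0

    def test_planted_families_recovered(self):
        pa, clade = self._matrix()
        hits = clade_specific_families(pa, clade)
        planted = [i for i in hits.index if i.startswith("planted_")]
        assert len(planted) == 10

    def test_monotone_in_thresholds(self):
        pa, clade = self._matrix()
        base = set(clade_specific_families(pa, clade, 0.8, 0.1).index)
        tighter_in = set(clade_specific_families(pa, clade, 0.95, 0.1).index)
        tighter_out = set(clade_specific_families(pa, clade, 0.8, 0.02).index)
        assert tighter_in <= base and tighter_out <= base

    def test_degenerate_clades_rejected(self):
        pa = pd.DataFrame({"g1": [1], "g2": [0]}, index=["famA"])
        with pytest.raises(ParameterDomainError):
            clade_specific_families(pa, [])
        with pytest.raises(ParameterDomainError):
            clade_specific_families(pa, ["g1", "g2"])


class TestGroupCompare:
    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        res = group_compare(np.r_[a, b], ["L"] * 20 + ["M"] * 20)
        assert res.p_value < 1e-3
        assert "L < M" in res.pairwise["direction"].iloc[0]

    def test_three_groups_kruskal_with_bh(self):
        rng = np.random.default_rng(2)
        vals = np.r_[rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                     rng.normal(4, 1, 15)]
        res = group_compare(vals, ["L"] * 15 + ["Lp"] * 15 + ["M"] * 15)
        assert res.overall_test == "Kruskal-Wallis"
        assert len(res.pairwise) == 3
        assert (res.pairwise["p_adj"] >= res.pairwise["p"] - 1e-12).all()

    def test_type_one_error_calibrated(self):
        hits = 0
        reps = 100
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            vals = rng.normal(0, 1, 40)
            res = group_compare(vals, ["A"] * 20 + ["B"] * 20)
            hits += res.p_value <= 0.05
        assert hits <= 6  # ~5% nominal; >= 94% of runs non-significant

    def test_all_tied_reports_boundary(self):
        res = group_compare([1.0] * 8, ["A"] * 4 + ["B"] * 4)
        assert res.p_value == 1.0
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterDomainError):
            group_compare([1.0, 2.0, 3.0], ["A", "A", "B"])
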