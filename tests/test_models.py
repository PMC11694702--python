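import numpy as np
import pytest

from phylotherm import simulate
from phylotherm.errors import NotUltrametricError, ParameterDomainError
from phylotherm.models import (ALL_FAMILIES, EvolModelSpec, TraitEvolution,
                               fit_all, fit_model, reml_loglik,
                               transform_tree)
from phylotherm.tree import Phylogeny

from conftest import random_tree
from oracles import mvn_reml, ou_cov, phylo_cov


def _bm(s2=1.0):
    return EvolModelSpec("BM", {"sigma2": s2})


class TestRemlLoglik:
    def test_cherry_closed_form(self, cherry):
        lnl = reml_loglik(cherry, {"A": 0.0, "B": 0.0}, _bm())
        assert lnl == pytest.approx(-0.5 * np.log(4 * np.pi), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bm_matches_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(4, 17)),
                           ultrametric=bool(seed % 2))
        vals = simulate.sim_trait(tree, _bm(1.5), seed=seed)
        x = np.array([vals[l] for l in tree.tip_labels])
        C = phylo_cov(tree)
        for s2 in (0.4, 1.5):
            assert reml_loglik(tree, vals, _bm(s2)) == \
                pytest.approx(mvn_reml(x, C, s2), abs=1e-8)

    def test_ou_matches_closed_form_covariance(self, yule20):
        vals = simulate.sim_trait(yule20, _bm(), seed=3)
        x = np.array([vals[l] for l in yule20.tip_labels])
        for alpha in (0.3, 1.5):
            spec = EvolModelSpec("OU", {"sigma2": 0.8, "ou_alpha": alpha})
            assert reml_loglik(yule20, vals, spec) == pytest.approx(
                mvn_reml(x, ou_cov(yule20, alpha), 0.8), abs=1e-8)

    def test_non_ultrametric_rejected_for_depth_transforms(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:5);")
        for fam, par in [("OU", {"sigma2": 1, "ou_alpha": 1}),
                         ("EB", {"sigma2": 1, "eb_rate": -1}),
                         ("delta", {"sigma2": 1, "pagel_delta": 2})]:
            with pytest.raises(NotUltrametricError):
                reml_loglik(t, {"A": 0, "B": 1, "C": 2},
                            EvolModelSpec(fam, par))


class TestTransforms:
    IDENTITY = [
        ("lambda", {"pagel_lambda": 1.0}),
        ("kappa", {"pagel_kappa": 1.0}),
        ("delta", {"pagel_delta": 1.0}),
        ("EB", {"eb_rate": 0.0}),
        ("rate_trend", {"trend_slope": 0.0}),
    ]

    @pytest.mark.parametrize("family,params", IDENTITY)
    def test_identity_limits(self, yule20, family, params):
        wt = transform_tree(yule20, family, params)
        assert np.allclose(wt.lengths, yule20.lengths, atol=1e-12)

    def test_lambda_zero_gives_star_covariance(self, yule20):
        wt = transform_tree(yule20, "lambda", {"pagel_lambda": 0.0})
        C = phylo_cov(wt)
        off = C[~np.eye(len(C), dtype=bool)]
        assert np.abs(off).max() < 1e-10
        assert np.allclose(np.diag(C), yule20.depths()[yule20.tip_ids])

    def test_lambda_preserves_tip_heights_nonultrametric(self):
        rng = np.random.default_rng(5)
        t = random_tree(rng, 12, ultrametric=False)
        wt = transform_tree(t, "lambda", {"pagel_lambda": 0.37})
        assert np.allclose(wt.depths()[wt.tip_ids],
                           t.depths()[t.tip_ids])

    def test_trend_slope_domain(self, yule20):
        bad = -1.5 / yule20.height
        with pytest.raises(ParameterDomainError):
            transform_tree(yule20, "rate_trend", {"trend_slope": bad})


class TestFit:
    def test_aic_arithmetic(self):
        from phylotherm.models import TraitEvolutionResult
        r = TraitEvolutionResult("OU", {}, loglik=-10.0, converged=True,
                                 n_restarts=1, n_iter=1, n_contrasts=5)
        assert r.aic == 24.0

    def test_bm_fit_recovers_profiled_sigma2(self, yule50):
        vals = simulate.sim_trait(yule50, _bm(2.0), seed=11)
        res = fit_model(yule50, vals, "BM")
        # profiled REML optimum: mean standardized squared contrast
        from phylotherm.contrasts import compute_contrasts
        cs = compute_contrasts(yule50, vals)
        assert res.params["sigma2"] == pytest.approx(
            np.mean(cs.contrasts ** 2 / cs.variances))
        assert res.aic == pytest.approx(2 - 2 * res.loglik)

    def test_nested_gaussian_never_beats_superset(self, yule50):
        vals = simulate.sim_trait(yule50, _bm(), seed=13)
        bm = fit_model(yule50, vals, "BM")
        for fam in ("lambda", "OU", "EB"):
            sup = fit_model(yule50, vals, fam)
            assert sup.loglik >= bm.loglik - 1e-6

    def test_aic_ranking_invariances(self, yule20):
        """Ranking unaffected by tip order; BM sigma2 scales as c^2 under
        trait rescaling with lnL shifted by (n-1) log c."""
        vals = simulate.sim_trait(yule20, _bm(), seed=17)
        r1 = fit_model(yule20, vals, "BM")
        perm = vals.sample(frac=1.0, random_state=1)
        r2 = fit_model(yule20, perm, "BM")
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-10)
        c = 3.0
        r3 = fit_model(yule20, vals * c, "BM")
        assert r3.params["sigma2"] == pytest.approx(
            c ** 2 * r1.params["sigma2"], rel=1e-10)
        n1 = yule20.n_tips - 1
        assert r3.loglik == pytest.approx(r1.loglik - n1 * np.log(c),
                                          abs=1e-8)

    def test_fit_all_table_sorted_with_daic(self, yule20):
        vals = simulate.sim_trait(yule20, _bm(), seed=19)
        sel = fit_all(yule20, vals, families=["BM", "lambda", "JN"],
                      restarts=2, seed=0)
        tab = sel.table
        assert list(tab.columns[:4]) == ["family", "k", "lnL", "AIC"]
        conv = tab[tab["converged"]]
        assert (conv["AIC"].diff().dropna() >= -1e-9).all()
        assert conv["dAIC"].iloc[0] == 0.0
        assert set(tab["family"]) == {"BM", "lambda", "JN"}

    def test_unknown_family_rejected(self, yule20):
        with pytest.raises(ParameterDomainError):
            TraitEvolution(yule20, simulate.sim_trait(yule20, _bm(), seed=1),
                           "bogus")


class TestNestedJumpIdentities:
    def test_bmjn_zero_rate_equals_bm(self, yule50):
        vals = simulate.sim_trait(yule50, _bm(), seed=23)
        bm = reml_loglik(yule50, vals, _bm())
        bmjn = reml_loglik(yule50, vals, EvolModelSpec(
            "BMJN", {"sigma2": 1.0, "jump_rate": 0.0, "jump_var": 1.0}))
        assert bmjn == pytest.approx(bm, abs=1e-6)
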