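"""Pagel's lambda, ancestral states, PGLS and phylogenetic (M)ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import alphamorph as am
from alphamorph.errors import CollinearityError, DesignError, RankError, SizeError
from alphamorph.phylo_comparative import _anova_f, _wilks
from alphamorph.synthetic_data import (
    SimulatedComparativeSpec,
    simulate_pure_birth_tree,
    simulate_tree_and_traits,
)

from oracles import rerooted_ancestral_state


def _bm(n=30, lam=1.0, seed=0, **kw):
    return simulate_tree_and_traits(
        SimulatedComparativeSpec(n_species=n, lambda_=lam, seed=seed, **kw)
    )


class TestPagelsLambda:
    def test_iid_limiting_case_loglik(self):
        # at lambda=0 the model is i.i.d. normal with shared tip variances
        phy, ds = _bm(20, seed=1)
        x = ds.traits["response"]
        res = am.pagels_lambda(phy, x)
        from alphamorph.phylo_comparative import _bm_profile_loglik, _pagel_cov

        labels, C = phy.covariance()
        xv = x.loc[labels].to_numpy()
        ll0 = _bm_profile_loglik(xv, np.ones((len(xv), 1)), _pagel_cov(C, 0.0))[0]
        # closed form for iid normal with per-tip variance sigma2*C_ii
        d = np.diag(C)
        mu = np.sum(xv / d) / np.sum(1 / d)
        s2 = np.mean((xv - mu) ** 2 / d)
        ll_ref = -0.5 * (len(xv) * np.log(2 * np.pi * s2) + np.log(d).sum() + len(xv))
        assert ll0 == pytest.approx(ll_ref, abs=1e-8)
        assert res.loglik0 == pytest.approx(ll0, abs=1e-8)

    def test_shuffled_trait_has_no_signal(self):
        rng = np.random.default_rng(0)
        lams = []
        for rep in range(10):
            phy, ds = _bm(60, lam=1.0, seed=200 + rep)
            x = ds.traits["response"].copy()
            x[:] = rng.permutation(x.to_numpy())
            lams.append(am.pagels_lambda(phy, x).lambda_)
        assert np.mean(lams) < 0.2

    def test_branch_scaling_invariance(self):
        phy, ds = _bm(25, seed=3)
        a = am.pagels_lambda(phy, ds.traits["response"])
        b = am.pagels_lambda(phy.scaled(7.3), ds.traits["response"])
        assert b.lambda_ == pytest.approx(a.lambda_, abs=1e-6)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-6)

    def test_too_few_tips(self):
        star = am.Phylogeny.star(["a", "b", "c"])
        with pytest.raises(SizeError):
            am.pagels_lambda(star, pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestAncestralStates:
    def test_two_tip_symmetric_mean(self):
        tr = am.Phylogeny.from_newick("(a:1,b:1);")
        anc = am.ancestral_states(tr, pd.Series({"a": 2.0, "b": 4.0}))
        assert anc.iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_constant_trait_everywhere(self):
        phy, _ = _bm(12, seed=4)
        anc = am.ancestral_states(phy, pd.Series(5.5, index=phy.tip_labels))
        np.testing.assert_allclose(anc.to_numpy(), 5.5, atol=1e-9)

    def test_matches_rerooting_oracle_on_8_tips(self):
        phy, ds = _bm(8, seed=9)
        trait = ds.traits["response"]
        anc = am.ancestral_states(phy, trait)
        vals = iter(anc.to_numpy())
        for node in phy.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            expected = rerooted_ancestral_state(phy.tree, node, trait)
            assert next(vals) == pytest.approx(expected, abs=1e-8)


class TestPgls:
    def test_lambda_zero_equals_ols(self):
        import statsmodels.api as sm

        phy, ds = _bm(40, slopes={"x": 0.3}, seed=6)
        fit = am.pgls(ds.traits, tree=phy, response="response", predictors=["x"],
                      lambda_=0.0)
        d = ds.traits.loc[sorted(ds.traits.index)]
        # lambda=0 leaves per-tip variances diag(C); on an ultrametric tree
        # these are equal, so GLS = OLS
        ols = sm.OLS(d["response"], sm.add_constant(d[["x"]])).fit()
        np.testing.assert_allclose(fit.coef["slope"].to_numpy(), ols.params.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(fit.coef["se"].to_numpy(), ols.bse.to_numpy(),
                                   atol=1e-8)

    def test_t_equals_slope_over_se(self):
        phy, ds = _bm(30, slopes={"x": 0.5}, seed=7)
        fit = am.pgls(ds.traits, tree=phy, response="response", predictors=["x"])
        np.testing.assert_allclose(
            fit.coef["t"], fit.coef["slope"] / fit.coef["se"], rtol=1e-12
        )
        assert ((fit.coef["p"] >= 0) & (fit.coef["p"] <= 1)).all()
        assert 0.0 <= fit.lambda_ <= 1.0

    def test_branch_scaling_invariance(self):
        phy, ds = _bm(25, slopes={"x": 0.4}, seed=8)
        a = am.pgls(ds.traits, tree=phy, response="response", predictors=["x"])
        b = am.pgls(ds.traits, tree=phy.scaled(13.0), response="response",
                    predictors=["x"])
        np.testing.assert_allclose(a.coef["slope"], b.coef["slope"], atol=1e-8)
        assert a.lambda_ == pytest.approx(b.lambda_, abs=1e-5)

    def test_collinear_design_raises(self):
        phy, ds = _bm(20, predictor_names=("x",), seed=10)
        t = ds.traits.copy()
        t["x2"] = 2.0 * t["x"]
        with pytest.raises(CollinearityError):
            am.pgls(t, tree=phy, response="response", predictors=["x", "x2"])

    def test_missing_species_dropped_per_model(self):
        phy, ds = _bm(20, slopes={"x": 0.5}, seed=11)
        t = ds.traits.copy()
        t.loc[t.index[0], "x"] = np.nan
        fit = am.pgls(t, tree=phy, response="response", predictors=["x"])
        assert fit.n == 19

    def test_multiple_regression_supported(self):
        phy, ds = _bm(30, slopes={"x": 0.5, "z": -0.2}, seed=12)
        fit = am.pgls(ds.traits, tree=phy, response="response",
                      predictors=["x", "z"])
        assert list(fit.coef.index) == ["intercept", "x", "z"]


class TestPhylAnova:
    def test_constant_trait_f_zero_p_one(self):
        phy, _ = _bm(16, seed=13)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=phy.tip_labels)
        res = am.phyl_anova(phy, pd.Series(2.0, index=phy.tip_labels), groups,
                            n_sim=99, seed=1)
        assert res.F == 0.0
        assert res.p_phylo == 1.0

    def test_classical_f_matches_scipy(self, rng):
        phy, ds = _bm(24, seed=14)
        x = ds.traits["response"]
        groups = pd.Series(rng.choice(["a", "b", "c"], size=24), index=x.index)
        res = am.phyl_anova(phy, x, groups, n_sim=49, seed=2)
        ref = stats.f_oneway(*[x[groups == g] for g in ["a", "b", "c"]])
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_classical == pytest.approx(ref.pvalue, rel=1e-8)

    def test_shifted_groups_detected_on_star_tree(self, rng):
        labels = [f"t{i:02d}" for i in range(30)]
        star = am.Phylogeny.star(labels)
        x = pd.Series(rng.normal(size=30), index=labels)
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=labels)
        x[groups == "b"] += 3.0 * x.std()
        res = am.phyl_anova(star, x, groups, n_sim=499, seed=3)
        assert res.p_phylo < 0.01

    def test_single_group_raises(self):
        phy, ds = _bm(10, seed=15)
        groups = pd.Series("only", index=phy.tip_labels)
        with pytest.raises(DesignError):
            am.phyl_anova(phy, ds.traits["response"], groups, n_sim=9, seed=0)


class TestPhylManova:
    def test_univariate_agrees_with_anova(self, rng):
        phy, ds = _bm(20, seed=16)
        x = ds.traits["response"]
        groups = pd.Series(rng.choice(["a", "b"], size=20), index=x.index)
        res_a = am.phyl_anova(phy, x, groups, n_sim=999, seed=5)
        res_m = am.phyl_manova(phy, x.to_frame(), groups, n_sim=999, seed=5)
        assert abs(res_a.p_phylo - res_m.p_phylo) < 0.08

    def test_wilks_invariant_under_rotation(self, rng):
        Y = rng.normal(size=(25, 3))
        g = rng.choice(["a", "b"], size=25)
        lam1, _ = _wilks(Y, g)
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        lam2, _ = _wilks(Y @ Q, g)
        assert lam2 == pytest.approx(lam1, rel=1e-9)

    def test_wilks_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        Y = rng.normal(size=(30, 2))
        g = rng.choice(["a", "b", "c"], size=30)
        lam, F = _wilks(Y, g)
        df = pd.DataFrame(Y, columns=["y1", "y2"])
        df["g"] = g
        mv = MANOVA.from_formula("y1 + y2 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        assert lam == pytest.approx(float(tab.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert F == pytest.approx(float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-6)

    def test_rank_error_when_too_many_dimensions(self, rng):
        phy, _ = _bm(6, seed=17)
        labels = phy.tip_labels
        Y = pd.DataFrame(rng.normal(size=(6, 5)), index=labels)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=labels)
        with pytest.raises(RankError):
            am.phyl_manova(phy, Y, groups, n_sim=9, seed=0)


class TestStarTreeReductions:
    def test_anova_vectorized_f_consistency(self, rng):
        Y = rng.normal(size=(7, 40))
        g = rng.choice(["a", "b", "c", "d"], size=40)
        ours = _anova_f(Y, g)
        for i in range(7):
            ref = stats.f_oneway(*[Y[i][g == c] for c in np.unique(g)]).statistic
            assert ours[i] == pytest.approx(ref, rel=1e-10)
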