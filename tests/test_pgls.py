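import time

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from weedshift.errors import NumericalError
from weedshift.pgls import (
    PGLS,
    fit_gls,
    fit_pgls_ml,
    lrt_lambda,
    pagel_transform,
    vcv_from_tree,
)
from weedshift.synthetic import TraitEvolConfig, gen_brownian_traits, gen_tree


class TestVCV:
    def test_root_cherry_has_zero_covariance(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick",
                                 preserve_underscores=True)
        V = vcv_from_tree(tree)
        assert np.allclose(V.to_numpy(), np.eye(2))

    def test_three_taxon_hand_count(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        assert V.loc["A", "B"] == 1.0
        assert V.loc["A", "C"] == 0.0
        assert np.allclose(np.diag(V.to_numpy()), 2.0)

    def test_star_tree_is_diagonal(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick",
                                 preserve_underscores=True)
        V = vcv_from_tree(tree).to_numpy()
        assert np.allclose(V, np.eye(4))

    def test_tip_order_and_missing_tip(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree, tip_order=["C", "A"])
        assert list(V.index) == ["C", "A"]
        with pytest.raises(KeyError, match="Z"):
            vcv_from_tree(three_taxon_tree, tip_order=["A", "Z"])

    def test_offdiagonal_bounded_by_diagonal(self):
        tree = gen_tree(40, seed=9)
        V = vcv_from_tree(tree).to_numpy()
        d = np.diag(V)
        assert np.all(V <= np.minimum.outer(d, d) + 1e-12)


class TestPagelTransform:
    def test_lambda_zero_is_star(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        T = pagel_transform(V, lam=0.0)
        assert np.allclose(T.to_numpy(), np.diag(np.diag(V.to_numpy())))

    def test_identity_transform(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        T = pagel_transform(V, lam=1.0, delta=1.0)
        assert np.array_equal(T.to_numpy(), V.to_numpy())

    def test_lambda_half_scales_offdiagonal_only(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        T = pagel_transform(V, lam=0.5)
        assert T.loc["A", "B"] == 0.5
        assert np.allclose(np.diag(T.to_numpy()), 2.0)

    def test_delta_powers_normalized_depths(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        T = pagel_transform(V, delta=2.0)
        # depth 2 normalizes to 1; shared depth 0.5 -> 0.25 -> rescaled 0.5
        assert T.loc["A", "B"] == pytest.approx(2.0 * 0.25)
        assert np.allclose(np.diag(T.to_numpy()), 2.0)

    def test_invalid_parameters(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        with pytest.raises(ValueError):
            pagel_transform(V, lam=1.5)
        with pytest.raises(ValueError):
            pagel_transform(V, delta=0.0)


class TestFitGLS:
    def test_identity_v_reduces_to_ols(self, rng):
        n = 40
        X = rng.normal(size=(n, 2))
        y = 1.0 + X @ np.array([0.5, -0.3]) + rng.normal(size=n)
        fit = fit_gls(y, X, np.eye(n))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, rtol=1e-10)
        np.testing.assert_allclose(fit.bse.to_numpy(), ols.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ols.pvalues,
                                   rtol=1e-8)
        assert fit.rsquared_adj == pytest.approx(ols.rsquared_adj, rel=1e-10)
        assert fit.fvalue == pytest.approx(ols.fvalue, rel=1e-10)

    def test_exact_linear_data(self, rng):
        n = 20
        X = rng.normal(size=(n, 2))
        y = X @ np.array([2.0, 3.0])
        fit = fit_gls(y, X, np.eye(n))
        assert fit.params.iloc[1] == pytest.approx(2.0, abs=1e-10)
        assert fit.params.iloc[2] == pytest.approx(3.0, abs=1e-10)
        assert np.allclose(fit.resid.to_numpy(), 0.0, atol=1e-10)
        assert fit.rsquared_adj == pytest.approx(1.0)

    def test_three_taxon_brute_force(self, three_taxon_tree):
        V = vcv_from_tree(three_taxon_tree)
        y = pd.Series([1.0, 2.0, 4.0], index=["A", "B", "C"])
        x = pd.Series([0.0, 1.0, 2.0], index=["A", "B", "C"], name="x")
        fit = PGLS(y, x, V=V).fit()
        # independent brute-force GLS: beta = (X' V^-1 X)^-1 X' V^-1 y
        Vi = np.linalg.inv(V.to_numpy())
        Xd = np.column_stack([np.ones(3), x.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-10)

    def test_scale_equivariance(self, rng):
        tree = gen_tree(30, seed=3)
        V = vcv_from_tree(tree)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=30, beta_true=(0.7,), seed=8)
        )
        f1 = PGLS(y, X, V=V).fit()
        f2 = PGLS(y, X, V=V * 7.3).fit()
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-9)
        np.testing.assert_allclose(f1.tvalues, f2.tvalues, rtol=1e-9)
        np.testing.assert_allclose(f1.pvalues, f2.pvalues, rtol=1e-9)

    def test_residual_orthogonality(self, rng):
        tree = gen_tree(25, seed=4)
        V = vcv_from_tree(tree)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=25, beta_true=(0.5,), seed=9)
        )
        fit = PGLS(y, X, V=V).fit()
        Vi = np.linalg.inv(V.to_numpy())
        Xd = np.column_stack([np.ones(25),
                              X.loc[fit.model.tip_order].to_numpy()])
        g = Xd.T @ Vi @ fit.resid.to_numpy()
        assert np.allclose(g, 0.0, atol=1e-8)

    def test_singular_design_raises(self):
        V = np.eye(5)
        X = np.ones((5, 2))  # duplicated constant column
        with pytest.raises(NumericalError):
            PGLS(np.arange(5.0), X, V=V, tip_order=list("abcde"),
                 add_intercept=False).fit()


class TestFitML:
    def test_fixed_ml_flags_match_fixed_fit_bitwise(self):
        tree = gen_tree(40, seed=5)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=40, lambda_true=1.0,
                                  beta_true=(0.4,), seed=10)
        )
        V = vcv_from_tree(tree)
        direct = fit_gls(y, X, V)
        via_ml_api = fit_pgls_ml(y, X, V, ml_lambda=False, ml_delta=False)
        assert direct.params.equals(via_ml_api.params)
        assert direct.llf == via_ml_api.llf

    def test_optimum_beats_grid(self):
        tree = gen_tree(50, seed=6)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=50, lambda_true=0.6,
                                  beta_true=(0.5,), seed=11)
        )
        model = PGLS(y, X, tree=tree)
        fit = model.fit(lam="ml")
        grid_lls = [model.loglik(l) for l in np.linspace(0, 1, 21)]
        assert fit.llf >= max(grid_lls) - 1e-9

    def test_lambda_recovery_smoke(self):
        hats = []
        for rep in range(15):
            tree = gen_tree(80, seed=300 + rep)
            y, X = gen_brownian_traits(
                tree, TraitEvolConfig(n_tips=80, lambda_true=1.0,
                                      beta_true=(0.5,), seed=400 + rep)
            )
            hats.append(PGLS(y, X, tree=tree).fit(lam="ml").lambda_hat)
        assert np.median(hats) > 0.85

    def test_joint_lambda_delta_runs(self):
        tree = gen_tree(40, seed=7)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=40, lambda_true=0.8,
                                  beta_true=(0.5,), seed=12)
        )
        fit = PGLS(y, X, tree=tree).fit(lam="ml", delta="ml")
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert 0.1 <= fit.delta_hat <= 3.0

    def test_paper_scale_fit_under_one_second(self):
        tree = gen_tree(95, seed=8)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=95, lambda_true=0.7,
                                  beta_true=(0.5,), seed=13)
        )
        model = PGLS(y, X, tree=tree)
        t0 = time.time()
        model.fit(lam="ml")
        assert time.time() - t0 < 1.0


class TestLRT:
    def test_identical_fits_give_zero(self):
        tree = gen_tree(30, seed=9)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=30, beta_true=(0.3,), seed=14)
        )
        fit = PGLS(y, X, tree=tree).fit(lam=0.5)
        stat, p = lrt_lambda(fit, fit)
        assert stat == 0.0
        assert p == 1.0

    def test_power_under_strong_signal(self):
        rejections = 0
        reps = 40
        for rep in range(reps):
            tree = gen_tree(100, seed=500 + rep)
            y, X = gen_brownian_traits(
                tree, TraitEvolConfig(n_tips=100, lambda_true=1.0,
                                      beta_true=(0.5,), seed=600 + rep)
            )
            model = PGLS(y, X, tree=tree)
            stat, p = lrt_lambda(model.fit(lam="ml"), model.fit(lam=0.0))
            rejections += p < 0.05
        assert rejections / reps > 0.8

    def test_optimizer_failure_detected(self):
        tree = gen_tree(60, seed=10)
        y, X = gen_brownian_traits(
            tree, TraitEvolConfig(n_tips=60, lambda_true=1.0,
                                  beta_true=(0.3,), seed=15)
        )
        model = PGLS(y, X, tree=tree)
        ml = model.fit(lam="ml")
        null = model.fit(lam=0.0)
        assert ml.llf > null.llf + 1e-6  # strong signal separates the fits
        with pytest.raises(NumericalError):
            # a supposed ML fit with lower likelihood than its null is a bug
            lrt_lambda(null, ml)


class TestFromDataFrame:
    def test_log_response_and_join(self, three_taxon_tree):
        data = pd.DataFrame(
            {"F": [0.5, 0.25, 0.125], "A": [1.0, 2.0, 3.0]},
            index=pd.Index(["A", "B", "C"], name="species"),
        )
        model = PGLS.from_dataframe(data, "F", ["A"], tree=three_taxon_tree,
                                    log_response=True)
        assert model.y == pytest.approx(np.log(data["F"]).to_numpy())

    def test_log_response_rejects_nonpositive(self, three_taxon_tree):
        data = pd.DataFrame(
            {"F": [0.5, 0.0, 0.1], "A": [1.0, 2.0, 3.0]},
            index=pd.Index(["A", "B", "C"], name="species"),
        )
        with pytest.raises(ValueError, match="B"):
            PGLS.from_dataframe(data, "F", ["A"], tree=three_taxon_tree,
                                log_response=True)
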