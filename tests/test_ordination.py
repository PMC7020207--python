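import numpy as np
import pandas as pd
import pytest

from weedshift.ordination import HillSmith, build_mixed_design, hill_smith
from weedshift.pgls import PGLS
from weedshift.synthetic import gen_traits


def quantitative_table(rng, n=40, p=6):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"t{i}" for i in range(p)],
        index=pd.Index([f"sp{i}" for i in range(n)], name="species"),
    )


class TestMixedDesign:
    def test_all_quantitative_is_zscore(self, rng):
        T = quantitative_table(rng)
        design = build_mixed_design(T)
        Z = design.Z.to_numpy()
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-12)

    def test_binary_trait_gives_complementary_columns(self):
        T = pd.DataFrame({"form": ["x", "x", "y", "x"]},
                         index=pd.Index(list("abcd"), name="species"))
        design = build_mixed_design(T)
        assert list(design.Z.columns) == ["form::x", "form::y"]
        Z = design.Z.to_numpy()
        # centered indicators: weighted means vanish, signs complementary
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.all(np.sign(Z[:, 0]) == -np.sign(Z[:, 1]))

    def test_column_count_matches_schema(self):
        # full mixed schema: 11 quantitative + 3+5+3+2 qualitative levels
        traits = gen_traits(95, seed=1)
        design = build_mixed_design(traits)
        n_levels = sum(traits[c].nunique() for c in design.qualitative)
        assert design.Z.shape[1] == len(design.quantitative) + n_levels

    def test_constant_trait_rejected(self):
        T = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]},
                         index=pd.Index(list("xyz"), name="species"))
        with pytest.raises(ValueError, match="constant"):
            build_mixed_design(T)

    def test_qualitative_inertia_is_levels_minus_one(self):
        T = pd.DataFrame({"form": ["x", "x", "y", "z", "z", "z"]},
                         index=pd.Index(list("abcdef"), name="species"))
        design = build_mixed_design(T)
        Z = design.Z.to_numpy()
        inertia = np.trace((Z * design.row_weights[:, None]).T @ Z)
        assert inertia == pytest.approx(2.0)  # 3 levels - 1


class TestHillSmith:
    def test_quantitative_eigenvalues_match_correlation_pca(self, rng):
        T = quantitative_table(rng)
        res = HillSmith(T).fit(n_axes=6)
        oracle = np.sort(np.linalg.eigvalsh(np.corrcoef(T.to_numpy().T)))[::-1]
        np.testing.assert_allclose(res.eigenvalues.to_numpy(), oracle,
                                   atol=1e-8)

    def test_trace_identity_on_mixed_table(self):
        traits = gen_traits(60, seed=2)
        design = build_mixed_design(traits)
        # indicator blocks are rank-deficient, so full-column requests warn
        with pytest.warns(UserWarning, match="rank"):
            res = hill_smith(design, n_axes=design.Z.shape[1])
        Z = design.Z.to_numpy()
        trace = np.trace((Z * design.row_weights[:, None]).T @ Z)
        assert res.eigenvalues.sum() == pytest.approx(trace, rel=1e-9)
        assert res.pct_inertia.sum() == pytest.approx(100.0 *
                                                      res.eigenvalues.sum()
                                                      / trace)

    def test_duplicated_species_get_identical_scores(self, rng):
        T = quantitative_table(rng, n=10)
        T2 = pd.concat([T, T.iloc[[0]].rename(index={"sp0": "dup"})])
        res = HillSmith(T2).fit(n_axes=3)
        np.testing.assert_allclose(res.row_scores.loc["sp0"],
                                   res.row_scores.loc["dup"], atol=1e-10)

    def test_row_scores_orthogonal_under_weights(self, rng):
        traits = gen_traits(50, seed=3)
        res = HillSmith(traits).fit(n_axes=5)
        S = res.row_scores.to_numpy()
        w = res.design.row_weights
        G = (S * w[:, None]).T @ S
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-9)
        np.testing.assert_allclose(np.diag(G),
                                   res.eigenvalues.to_numpy(), rtol=1e-9)

    def test_row_order_invariance(self, rng):
        traits = gen_traits(30, seed=4)
        res1 = HillSmith(traits).fit(n_axes=4)
        shuffled = traits.sample(frac=1.0, random_state=0)
        res2 = HillSmith(shuffled).fit(n_axes=4)
        np.testing.assert_allclose(
            res1.row_scores.loc[traits.index].to_numpy(),
            res2.row_scores.loc[traits.index].to_numpy(), atol=1e-9,
        )

    def test_rank_deficient_request_truncates_with_warning(self, rng):
        T = quantitative_table(rng, n=20, p=3)
        T["t3"] = T["t0"] + T["t1"]  # collinear column
        with pytest.warns(UserWarning, match="rank"):
            res = HillSmith(T).fit(n_axes=4)
        assert res.n_axes == 3


class TestContributions:
    def test_single_variable_loads_fully_on_axis1(self):
        T = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]},
                         index=pd.Index(list("wxyz"), name="species"))
        res = HillSmith(T).fit(n_axes=1)
        contrib = res.contributions()
        assert contrib.loc["a", "Axis1"] == pytest.approx(100.0)

    def test_orthogonal_variables_own_their_axes(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        T = pd.DataFrame({"a": x, "b": 2 * y},
                         index=pd.Index(list("wxyz"), name="species"))
        res = HillSmith(T).fit(n_axes=2)
        contrib = res.contributions().abs()
        assert sorted(contrib["Axis1"].round(6)) == [0.0, 100.0]
        assert sorted(contrib["Axis2"].round(6)) == [0.0, 100.0]

    def test_absolute_contributions_sum_to_100_per_axis(self):
        traits = gen_traits(40, seed=5)
        res = HillSmith(traits).fit(n_axes=6)
        sums = res.contributions().abs().sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 100.0, rtol=1e-9)

    def test_sign_flip_coherence(self, rng):
        T = quantitative_table(rng, n=25, p=3)
        res1 = HillSmith(T).fit(n_axes=3)
        T2 = T.copy()
        T2["t1"] = -T2["t1"]
        res2 = HillSmith(T2).fit(n_axes=3)
        c1 = res1.contributions()
        c2 = res2.contributions()
        # magnitudes are unchanged by negating an input column
        np.testing.assert_allclose(c1.abs().to_numpy(), c2.abs().to_numpy(),
                                   atol=1e-9)

    def test_trait_aggregation_covers_all_columns(self):
        traits = gen_traits(40, seed=6)
        res = HillSmith(traits).fit(n_axes=3)
        agg = res.trait_contributions()
        assert set(agg.index) == set(traits.columns)


class TestAxesAsPredictors:
    def test_axis_count_and_join_keys(self):
        traits = gen_traits(50, seed=7)
        res = HillSmith(traits).fit(n_axes=6)
        preds = res.axes_as_predictors([1, 2, 3, 4, 5, 6])
        assert preds.shape == (50, 6)
        assert list(preds.index) == list(traits.index)

    def test_unknown_axis_rejected(self):
        traits = gen_traits(20, seed=8)
        res = HillSmith(traits).fit(n_axes=2)
        with pytest.raises(ValueError):
            res.axes_as_predictors([5])

    def test_single_trait_axis_reproduces_single_trait_pgls(self, rng):
        # with one quantitative trait, axis 1 is the z-scored trait itself,
        # so PGLS on the axis must match PGLS on the standardized trait
        from weedshift.synthetic import gen_tree

        n = 30
        tree = gen_tree(n, seed=9)
        species = [lf.taxon.label for lf in tree.leaf_node_iter()]
        T = pd.DataFrame({"a": rng.normal(size=n)},
                         index=pd.Index(species, name="species"))
        res = HillSmith(T).fit(n_axes=1)
        y = pd.Series(rng.normal(size=n), index=species)
        z = (T["a"] - T["a"].mean()) / T["a"].std(ddof=0)
        fit_axis = PGLS(y, res.axes_as_predictors([1]), tree=tree).fit()
        fit_trait = PGLS(y, z.to_frame("a"), tree=tree).fit()
        assert abs(fit_axis.tvalues.iloc[1]) == pytest.approx(
            abs(fit_trait.tvalues.iloc[1]), rel=1e-9
        )
        assert fit_axis.pvalues.iloc[1] == pytest.approx(
            fit_trait.pvalues.iloc[1], rel=1e-9
        )
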