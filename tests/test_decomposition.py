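"""Two-fold decomposition: design coding, weighted logit, Yun/Fairlie
detailed contributions, bootstrap, and the core accounting identities."""

import numpy as np
import pandas as pd
import pytest

from samgap import (
    ModelSpec,
    SeparationError,
    ZeroLinearGapError,
    bootstrap_components,
    build_design,
    decompose_two_fold,
    fairlie_detailed,
    fit_weighted_logit,
    percent_contributions,
    yun_detailed,
)
from samgap.synthetic import default_config, generate_population

from conftest import DEFAULT_COVARIATES, weighted_mean


def toy_records(n=40, seed=0, p_base=0.3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cluster_id": rng.integers(0, 6, n).astype(str),
            "weight": rng.lognormal(0, 0.2, n),
            "residence": np.where(rng.random(n) < 0.5, "rural", "urban"),
            "edu": rng.choice(["none", "primary", "secondary"], n),
            "age": rng.normal(2.5, 1.2, n),
            "sam": (rng.random(n) < p_base).astype(int),
        }
    )
    return df


SPEC2 = ModelSpec(outcome="sam", covariates={"edu": "categorical", "age": "continuous"})


class TestBuildDesign:
    def test_two_level_categorical_coding(self):
        df = pd.DataFrame(
            {
                "cluster_id": ["a"] * 4 + ["b"] * 4,
                "weight": 1.0,
                "residence": ["rural", "rural", "urban", "urban"] * 2,
                "x": ["lo", "hi", "lo", "hi"] * 2,
                "sam": [0, 1, 0, 1, 1, 0, 1, 0],
            }
        )
        spec_raw = ModelSpec(outcome="sam", covariates={"x": "categorical"}, normalize=False)
        dd = build_design(df, spec_raw)
        assert dd.columns == ["intercept", "x[lo]"]  # levels sorted, 'hi' is base
        assert set(np.unique(dd.X_rural[:, 1])) == {0.0, 1.0}
        spec_dev = ModelSpec(outcome="sam", covariates={"x": "categorical"}, normalize=True)
        dd2 = build_design(df, spec_dev)
        assert set(np.unique(dd2.X_rural[:, 1])) == {-1.0, 1.0}  # deviation contrast

    def test_hand_coded_matrix(self):
        df = pd.DataFrame(
            {
                "cluster_id": "c",
                "weight": 1.0,
                "residence": ["rural", "rural", "urban", "urban"],
                "edu": ["none", "primary", "none", "primary"],
                "age": [1.0, 2.0, 3.0, 4.0],
                "sam": [0, 1, 0, 1],
            }
        )
        spec = ModelSpec(
            outcome="sam", covariates={"edu": "categorical", "age": "continuous"}, normalize=False
        )
        dd = build_design(df, spec)
        # levels sorted: base 'none', dummy 'primary'
        np.testing.assert_array_equal(dd.X_rural, [[1, 0, 1], [1, 1, 2]])
        np.testing.assert_array_equal(dd.X_urban, [[1, 0, 3], [1, 1, 4]])
        assert dd.terms == {"edu": [1], "age": [2]}

    def test_missing_rows_counted(self):
        df = toy_records(30, seed=1)
        df.loc[3, "age"] = np.nan
        df.loc[7, "edu"] = np.nan
        dd = build_design(df, SPEC2)
        assert dd.n_excluded == 2
        assert len(dd.X_rural) + len(dd.X_urban) == 28

    def test_level_missing_in_one_group_named(self):
        df = toy_records(30, seed=2)
        df.loc[df.residence == "urban", "edu"] = "primary"
        df.loc[df.residence == "rural", "edu"] = np.where(
            np.arange((df.residence == "rural").sum()) % 2, "primary", "none"
        )
        with pytest.raises(ValueError, match="none"):
            build_design(df, SPEC2)


class TestWeightedLogit:
    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        y = (rng.random(300) < 0.4).astype(float)
        w = rng.lognormal(0, 0.3, 300)
        f1 = fit_weighted_logit(X, y, w)
        f2 = fit_weighted_logit(X, y, 7.3 * w)
        np.testing.assert_allclose(f1.params, f2.params, rtol=1e-8)

    def test_constant_outcome_rejected(self):
        X = np.ones((20, 1))
        with pytest.raises(ValueError):
            fit_weighted_logit(X, np.zeros(20), np.ones(20))

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        X = np.column_stack([np.ones(40), x])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_weighted_logit(X, y, np.ones(40))

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        eta = -1.0 + 0.6 * X[:, 1] - 0.4 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w = rng.lognormal(0, 0.3, n)
        fit = fit_weighted_logit(X, y, w)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        np.testing.assert_allclose(fit.params, ref.params, rtol=1e-7)

    def test_monte_carlo_coefficient_recovery(self):
        rng = np.random.default_rng(5)
        n = 20000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
        beta = np.array([-2.0, 0.5, -0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        fit = fit_weighted_logit(X, y, np.ones(n))
        se = fit.bse()
        assert np.all(np.abs(fit.params - beta) < 3 * se)


class TestTwoFoldDecomposition:
    @pytest.mark.parametrize("reference", ["pooled", "rural", "urban"])
    def test_identity_all_references(self, small_world, model_spec, reference):
        res = decompose_two_fold(small_world, model_spec, reference=reference)
        assert res.explained + res.unexplained == pytest.approx(res.gap, abs=1e-10)

    def test_identical_groups_give_zero_components(self):
        rural = toy_records(60, seed=8)
        rural["residence"] = "rural"
        urban = rural.copy()
        urban["residence"] = "urban"
        df = pd.concat([rural, urban], ignore_index=True)
        res = decompose_two_fold(df, SPEC2)
        assert abs(res.gap) < 1e-10
        assert abs(res.explained) < 1e-10
        assert abs(res.unexplained) < 1e-10

    def test_linear_link_matches_closed_form(self, small_world, model_spec):
        res = decompose_two_fold(small_world, model_spec, reference="rural", link="identity")
        dd = build_design(small_world, model_spec)
        # classic linear Blinder-Oaxaca: explained = (xbar_R - xbar_U)' beta_R
        beta_r = np.linalg.solve(
            dd.X_rural.T @ (dd.X_rural * dd.w_rural[:, None]),
            dd.X_rural.T @ (dd.w_rural * dd.y_rural),
        )
        xbar_r = (dd.X_rural * dd.w_rural[:, None]).sum(0) / dd.w_rural.sum()
        xbar_u = (dd.X_urban * dd.w_urban[:, None]).sum(0) / dd.w_urban.sum()
        explained = (xbar_r - xbar_u) @ beta_r
        gap = weighted_mean(dd.y_rural, dd.w_rural) - weighted_mean(dd.y_urban, dd.w_urban)
        assert res.explained == pytest.approx(explained, abs=1e-8)
        assert res.gap == pytest.approx(gap, abs=1e-12)
        assert res.unexplained == pytest.approx(gap - explained, abs=1e-8)

    def test_label_swap_negates_components(self, small_world, model_spec):
        res = decompose_two_fold(small_world, model_spec)
        swapped = small_world.copy()
        swapped["residence"] = swapped["residence"].map({"rural": "urban", "urban": "rural"})
        res_sw = decompose_two_fold(swapped, model_spec)
        assert res_sw.gap == pytest.approx(-res.gap, abs=1e-10)
        assert res_sw.explained == pytest.approx(-res.explained, abs=1e-6)
        assert res_sw.unexplained == pytest.approx(-res.unexplained, abs=1e-6)

    def test_base_category_invariance_under_normalization(self, small_world):
        spec = ModelSpec(outcome="sam", covariates=DEFAULT_COVARIATES, normalize=True)
        res = decompose_two_fold(small_world, spec)
        relabeled = small_world.copy()
        # move the base wealth level to the top of the sort order
        relabeled["wealth"] = relabeled["wealth"].map(
            {1.0: "q5", 2.0: "q4", 3.0: "q3", 4.0: "q2", 5.0: "q1"}
        )
        res2 = decompose_two_fold(relabeled, spec)
        assert res2.detailed["wealth"]["contribution"] == pytest.approx(
            res.detailed["wealth"]["contribution"], abs=1e-6
        )


class TestYunDetailed:
    def test_single_covariate_takes_everything(self):
        out = yun_detailed([1.0, 0.4], [1.0, 0.1], [0.2, 1.5], explained=0.03,
                           terms={"x": [1]})
        assert out["x"]["weight"] == pytest.approx(1.0)
        assert out["x"]["contribution"] == pytest.approx(0.03)

    def test_hand_arithmetic_and_zero_denominator(self):
        xbar_r, xbar_u = [0.2, -0.1], [0.0, 0.0]
        with pytest.raises(ZeroLinearGapError):
            yun_detailed(xbar_r, xbar_u, [1.0, 2.0], explained=0.05)
        out = yun_detailed(xbar_r, xbar_u, [1.0, 1.5], explained=0.05)
        assert out["x0"]["weight"] == pytest.approx(4.0)
        assert out["x1"]["weight"] == pytest.approx(-3.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            k = rng.integers(2, 7)
            out = yun_detailed(rng.normal(size=k), rng.normal(size=k), rng.normal(size=k), 0.1)
            assert sum(e["weight"] for e in out.values()) == pytest.approx(1.0, abs=1e-10)

    def test_sums_to_explained_on_real_fit(self, small_world, model_spec):
        res = decompose_two_fold(small_world, model_spec)
        total = sum(e["contribution"] for e in res.detailed.values())
        assert total == pytest.approx(res.explained, abs=1e-10)


class TestFairlie:
    @pytest.fixture(scope="class")
    def balanced_world(self):
        """Equal group sizes, unit weights: matching uses both full groups."""
        rng = np.random.default_rng(11)
        n = 400
        x_r = rng.normal(0.8, 1.0, n)
        x_u = rng.normal(0.0, 1.0, n)
        df = pd.DataFrame(
            {
                "cluster_id": np.tile(np.arange(20).astype(str), 2 * n // 20),
                "weight": 1.0,
                "residence": ["rural"] * n + ["urban"] * n,
                "x": np.concatenate([x_r, x_u]),
                "sam": (rng.random(2 * n) < 0.3).astype(int),
            }
        )
        return df

    def test_single_covariate_equals_explained(self, balanced_world):
        spec = ModelSpec(outcome="sam", covariates={"x": "continuous"})
        res = decompose_two_fold(balanced_world, spec)
        fr = fairlie_detailed(balanced_world, spec, replications=3, seed=0)
        assert fr["x"]["contribution"] == pytest.approx(res.explained, abs=1e-12)

    def test_seed_determinism(self, small_world, model_spec):
        a = fairlie_detailed(small_world, model_spec, replications=5, seed=42)
        b = fairlie_detailed(small_world, model_spec, replications=5, seed=42)
        assert a == b

    def test_null_covariate_contributes_nothing(self):
        # one strong covariate, one with identical distributions and no effect
        rng = np.random.default_rng(13)
        n = 3000
        strong = np.concatenate([rng.normal(1.0, 1, n), rng.normal(0.0, 1, n)])
        null = rng.normal(0, 1, 2 * n)
        eta = -1.5 - 0.8 * strong
        df = pd.DataFrame(
            {
                "cluster_id": np.tile(np.arange(50).astype(str), 2 * n // 50),
                "weight": 1.0,
                "residence": ["rural"] * n + ["urban"] * n,
                "strong": strong,
                "null": null,
                "sam": (rng.random(2 * n) < 1 / (1 + np.exp(-eta))).astype(int),
            }
        )
        spec = ModelSpec(outcome="sam", covariates={"strong": "continuous", "null": "continuous"})
        fr = fairlie_detailed(df, spec, replications=50, seed=3)
        assert abs(fr["null"]["contribution"]) < 2 * fr["null"]["mc_se"] + 1e-4
        assert abs(fr["strong"]["contribution"]) > 10 * fr["strong"]["mc_se"]

    def test_replication_floor(self, small_world, model_spec):
        with pytest.raises(ValueError):
            fairlie_detailed(small_world, model_spec, replications=0)


class TestBootstrap:
    def test_minimum_replicates_enforced(self, small_world, model_spec):
        with pytest.raises(ValueError):
            bootstrap_components(small_world, model_spec, B=50, seed=0)

    def test_seed_determinism_and_shape(self, small_world, model_spec):
        a = bootstrap_components(small_world, model_spec, B=100, seed=7)
        b = bootstrap_components(small_world, model_spec, B=100, seed=7)
        assert a.intervals == b.intervals
        assert set(a.intervals) == {"gap", "explained", "unexplained", *DEFAULT_COVARIATES}
        for lo, hi in a.intervals.values():
            assert lo <= hi


class TestPercentContributions:
    def test_split_and_additivity(self, small_world, model_spec):
        res = decompose_two_fold(small_world, model_spec)
        pct = percent_contributions(res)
        assert pct["explained"] + pct["unexplained"] == pytest.approx(100.0, abs=1e-8)
        detail_sum = sum(pct[name] for name in DEFAULT_COVARIATES)
        assert detail_sum == pytest.approx(pct["explained"], abs=1e-8)

    def test_zero_gap_rejected(self, small_world, model_spec):
        res = decompose_two_fold(small_world, model_spec)
        res.gap = 0.0
        with pytest.raises(ValueError):
            percent_contributions(res)
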