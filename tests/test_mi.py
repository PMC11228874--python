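"""Chained-equation imputation: univariate imputers, FCS engine, pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from missim import (
    FAST_LIBRARY,
    ImputationSpec,
    fcs_impute,
    generate_complete,
    impute_cart,
    impute_logistic,
    impute_pmm,
    impute_rf,
    rubin_pool,
)
from missim.mi import (
    PoolSizeError,
    UnimputableVariableError,
    mi_method_map,
    mi_predictor_sets,
)


@pytest.fixture()
def linear_mcar(rng):
    n = 10_000
    x = rng.standard_normal((n, 2))
    y = 1.0 + 2.0 * x[:, 0] - x[:, 1] + rng.standard_normal(n)
    obs = rng.random(n) < 0.7
    return y, x, obs


class TestImputeLogistic:
    def test_marginal_preserved_with_null_covariates(self, rng):
        n = 20_000
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < 0.3).astype(float)  # independent of X
        obs = rng.random(n) < 0.7
        imp = impute_logistic(y[obs], X[obs], X[~obs], rng)
        assert imp.mean() == pytest.approx(0.3, abs=0.02)

    def test_fixed_coefficients_deterministic_probabilities(self, rng):
        beta = np.array([0.0, 1.0, -1.0])
        X = rng.standard_normal((5000, 2))
        y = (rng.random(5000) < expit(X @ beta[1:])).astype(float)
        imp = impute_logistic(y[:4000], X[:4000], X[4000:], rng,
                              beta_override=beta)
        p = expit(np.column_stack([np.ones(1000), X[4000:]]) @ beta)
        # draws are Bernoulli(p): the mean matches the average probability
        assert imp.mean() == pytest.approx(p.mean(), abs=0.06)

    def test_single_class_falls_back_to_constant(self, rng):
        X = rng.standard_normal((100, 1))
        with pytest.warns(UserWarning):
            imp = impute_logistic(np.ones(50), X[:50], X[50:], rng)
        assert (imp == 1).all()


class TestImputePmm:
    def test_support_preservation(self, linear_mcar, rng):
        y, x, obs = linear_mcar
        imp = impute_pmm(y[obs], x[obs], x[~obs], 5, rng)
        assert np.isin(imp, y[obs]).all()

    def test_single_donor_returns_nearest(self, rng):
        y_obs = np.array([0.0, 10.0, 20.0])
        X_obs = np.array([[0.0], [1.0], [2.0]])
        X_mis = np.array([[0.98]])
        vals = {float(impute_pmm(y_obs, X_obs, X_mis, 1,
                                 np.random.default_rng(s))[0])
                for s in range(20)}
        # donors are observed values; the modal pick is the middle one
        assert vals <= {0.0, 10.0, 20.0}
        assert 10.0 in vals

    def test_conditional_mean_recovered(self, linear_mcar, rng):
        y, x, obs = linear_mcar
        imp = impute_pmm(y[obs], x[obs], x[~obs], 5, rng)
        truth = 1.0 + 2.0 * x[~obs, 0] - x[~obs, 1]
        assert np.mean(imp - truth) == pytest.approx(0.0, abs=0.05)

    def test_pool_size_error(self, rng):
        with pytest.raises(PoolSizeError):
            impute_pmm(np.arange(3.0), np.zeros((3, 1)), np.zeros((1, 1)),
                       5, rng)


class TestImputeCart:
    def test_single_leaf_draws_from_margin(self, rng):
        y_obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        X_obs = np.zeros((20, 1))  # nothing to split on
        imp = impute_cart(y_obs, X_obs, np.zeros((50, 1)), None, rng)
        assert np.isin(imp, y_obs).all()
        assert len(np.unique(imp)) > 1

    def test_perfect_split_respected(self, rng):
        # binary predictor exactly determines the class
        X_obs = np.repeat([[0.0], [1.0]], 50, axis=0)
        y_obs = X_obs[:, 0]
        X_mis = np.array([[0.0], [1.0], [1.0]])
        imp = impute_cart(y_obs, X_obs, X_mis, {"min_samples_leaf": 5}, rng)
        assert np.allclose(imp, X_mis[:, 0])

    def test_support_preservation(self, linear_mcar, rng):
        y, x, obs = linear_mcar
        imp = impute_cart(y[obs], x[obs], x[~obs], None, rng)
        assert np.isin(imp, y[obs]).all()


class TestImputeRf:
    def test_support_preservation(self, linear_mcar, rng):
        y, x, obs = linear_mcar
        imp = impute_rf(y[obs], x[obs], x[~obs], None, rng)
        assert np.isin(imp, y[obs]).all()

    def test_single_tree_full_features_matches_cart(self):
        # T=1, no bootstrap, all features: the forest collapses to one tree
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        X_obs = np.repeat([[0.0], [1.0]], 50, axis=0)
        y_obs = X_obs[:, 0]
        X_mis = np.array([[0.0], [1.0]])
        rf = impute_rf(y_obs, X_obs, X_mis,
                       {"n_trees": 1, "bootstrap": False, "max_features": 1,
                        "min_samples_leaf": 5}, rng1)
        cart = impute_cart(y_obs, X_obs, X_mis,
                           {"min_samples_leaf": 5, "ccp_alpha": 0.0}, rng2)
        assert np.allclose(rf, cart)

    def test_default_split_candidates_is_sqrt_p(self):
        # p = 4 predictors: floor(sqrt(4)) = 2 variables tried per split
        p = 4
        assert max(1, int(np.floor(np.sqrt(p)))) == 2


class TestFcsImpute:
    def _spec(self, flavor="main", m=3, seed=0):
        return ImputationSpec(m=m, max_iter=3,
                              method_map=mi_method_map(flavor),
                              predictor_sets=mi_predictor_sets(flavor),
                              seed=seed)

    def test_complete_data_returns_identical_copies(self, small_cohort):
        stack = fcs_impute(small_cohort, self._spec())
        for d in stack.datasets:
            assert d.equals(small_cohort)

    def test_observed_entries_never_altered(self, simple_params):
        df = generate_complete(simple_params, 3000, 8)
        rng = np.random.default_rng(9)
        inc = df.copy()
        inc.loc[rng.random(3000) < 0.3, "Z2"] = np.nan
        inc.loc[rng.random(3000) < 0.2, "Y"] = np.nan
        stack = fcs_impute(inc, self._spec())
        obs_z2 = inc["Z2"].notna()
        obs_y = inc["Y"].notna()
        for d in stack.datasets:
            assert np.array_equal(d.loc[obs_z2, "Z2"], inc.loc[obs_z2, "Z2"])
            assert np.array_equal(d.loc[obs_y, "Y"], inc.loc[obs_y, "Y"])
            assert not d.isna().any().any()

    def test_determinism(self, simple_params):
        df = generate_complete(simple_params, 1500, 10)
        inc = df.copy()
        inc.loc[np.random.default_rng(11).random(1500) < 0.3, "X"] = np.nan
        s1 = fcs_impute(inc, self._spec(seed=4))
        s2 = fcs_impute(inc, self._spec(seed=4))
        for a, b in zip(s1.datasets, s2.datasets):
            assert a.equals(b)

    def test_mcar_binary_prevalence_matched(self, simple_params):
        df = generate_complete(simple_params, 10_000, 12)
        inc = df.copy()
        inc.loc[np.random.default_rng(13).random(10_000) < 0.3, "Z3"] = np.nan
        stack = fcs_impute(inc, self._spec(m=2))
        observed_prev = inc["Z3"].mean()
        for d in stack.datasets:
            imputed = d.loc[inc["Z3"].isna(), "Z3"]
            assert imputed.mean() == pytest.approx(observed_prev, abs=0.03)

    def test_chain_diagnostics_stabilize(self, simple_params):
        df = generate_complete(simple_params, 5000, 14)
        inc = df.copy()
        rng = np.random.default_rng(15)
        inc.loc[rng.random(5000) < 0.25, "Y"] = np.nan
        spec = ImputationSpec(m=3, max_iter=5,
                              method_map=mi_method_map("main"),
                              predictor_sets=mi_predictor_sets("main"),
                              seed=1)
        stack = fcs_impute(inc, spec)
        means = stack.chain_means["Y"]
        sds = stack.chain_sds["Y"]
        drift = np.abs(means[:, -1] - means[:, -2])
        assert (drift < 3 * sds[:, -1]).all()

    def test_unimputable_variable_raises(self, small_cohort):
        inc = small_cohort.copy()
        inc["Y"] = np.nan
        with pytest.raises(UnimputableVariableError):
            fcs_impute(inc, self._spec())

    def test_passive_terms_exclude_target(self):
        sets = mi_predictor_sets("2way")
        for var, terms in sets.items():
            for t in terms:
                assert var not in t.split("*")
        higher = mi_predictor_sets("higher")
        assert any(t.count("*") == 3 for t in higher["Z2"])
        with pytest.raises(ValueError):
            ImputationSpec(method_map={}, predictor_sets={"X": ["X*Z1"]}
                           ).validate()


class TestRubinPool:
    def test_hand_example(self):
        # psi = {0.1, 0.3}, se = {0.2, 0.2}
        pooled = rubin_pool([0.1, 0.3], [0.2, 0.2])
        assert pooled.psi_bar == pytest.approx(0.2)
        assert pooled.W == pytest.approx(0.04)
        assert pooled.B == pytest.approx(0.02)
        assert pooled.T == pytest.approx(0.07)
        assert pooled.se == pytest.approx(np.sqrt(0.07), abs=1e-10)

    def test_identical_estimates_collapse_to_within_variance(self):
        pooled = rubin_pool([0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        assert pooled.B == 0.0
        assert pooled.T == pooled.W
        assert np.isinf(pooled.df)

    def test_order_invariance(self):
        a = rubin_pool([0.1, 0.2, 0.4], [0.1, 0.2, 0.15])
        b = rubin_pool([0.4, 0.1, 0.2], [0.15, 0.1, 0.2])
        assert a.psi_bar == pytest.approx(b.psi_bar, abs=1e-12)
        assert a.T == pytest.approx(b.T, abs=1e-12)
        assert a.df == pytest.approx(b.df, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rubin_pool([0.1], [0.1])
        with pytest.raises(ValueError):
            rubin_pool([0.1, 0.2], [-0.1, 0.1])


class TestCongeniality:
    def test_mi_then_tmle_recovers_truth_under_mcar(self, simple_params):
        """Main-effects MI is congenial with the simple-scenario analysis:
        over replications, MI + TMLE recovers the true effect."""
        from missim.study import MethodID, StudyConfig, apply_method

        rng = np.random.default_rng(100)
        cfg = StudyConfig(library=FAST_LIBRARY, m=3, mi_cycles=3)
        estimates = []
        n_rep, n = 60, 1000
        for rep in range(n_rep):
            df = generate_complete(simple_params, n, 200 + rep)
            inc = df.copy()
            inc.loc[rng.random(n) < 0.25, "Y"] = np.nan
            inc.loc[rng.random(n) < 0.2, "Z2"] = np.nan
            res = apply_method(MethodID.MI_NO_INT, inc,
                               StudyConfig(library=FAST_LIBRARY, m=3,
                                           mi_cycles=3, seed=300 + rep))
            estimates.append(res.psi)
        mc_se = np.std(estimates) / np.sqrt(n_rep)
        assert np.mean(estimates) == pytest.approx(0.2, abs=2.5 * mc_se)


class TestRubinPoolProperties:
    """Algebraic invariants of Rubin's rules over arbitrary inputs."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=12),
           st.lists(st.floats(0, 3), min_size=12, max_size=12))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_total_variance_dominates_within(self, estimates, ses):
        pooled = rubin_pool(estimates, ses[:len(estimates)])
        assert pooled.T >= pooled.W - 1e-12
        assert pooled.B >= 0
        assert pooled.ci_low <= pooled.psi_bar <= pooled.ci_high

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=8, unique=True),
           st.integers(0, 6))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_permutation_invariance(self, estimates, shift):
        import numpy as np
        ses = [0.1 + 0.01 * i for i in range(len(estimates))]
        order = np.roll(np.arange(len(estimates)), shift)
        a = rubin_pool(estimates, ses)
        b = rubin_pool([estimates[i] for i in order], [ses[i] for i in order])
        assert a.psi_bar == pytest.approx(b.psi_bar, abs=1e-12)
        assert a.T == pytest.approx(b.T, abs=1e-12)
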