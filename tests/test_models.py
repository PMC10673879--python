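"""Base ISD learners: oracles, parameter recovery, invariants."""

import numpy as np
import pytest

from alsurv.curves import CensoredSample, km_fit, median_survival_time, survival_at
from alsurv.models import (
    AFTModel,
    ConvergenceError,
    CoxKPModel,
    MTLRModel,
    RSFModel,
    TimeGrid,
    cox_newton,
)
from alsurv.models.mtlr import _neg_log_posterior
from alsurv.models.rsf import _na_survival
from alsurv.synthetic import SimConfig, simulate_cohort

from conftest import feature_matrix, random_censored_sample


def assert_valid_curves(curves):
    for c in curves:
        assert c.knot_times[0] == 0.0
        assert c.knot_survival[0] == 1.0
        assert np.all(np.diff(c.knot_times) > 0)
        assert np.all(np.diff(c.knot_survival) <= 1e-12)
        assert np.all((c.knot_survival >= 0) & (c.knot_survival <= 1))


def breslow_partial_loglik(beta, X, times, events):
    """Independent scalar-oracle version of the Breslow partial likelihood."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            at_risk = times >= times[i]
            ll += X[i] @ beta - np.log(np.sum(np.exp(X[at_risk] @ beta)))
    return ll


class TestCoxKP:
    def test_null_model_baseline_equals_km(self, rng):
        y = random_censored_sample(rng, n=40)
        X = feature_matrix(np.full((40, 1), 3.0))  # constant feature: beta -> 0
        m = CoxKPModel().fit(X, y)
        km = km_fit(y)
        assert np.abs(m.beta_[0]) < 1e-8
        np.testing.assert_array_equal(m.baseline_.knot_times, km.knot_times)
        np.testing.assert_allclose(m.baseline_.knot_survival, km.knot_survival, atol=1e-10)

    def test_beta_matches_grid_oracle(self):
        # one binary covariate, 6 patients, no ties
        X = np.array([[0.0], [1.0], [0.0], [1.0], [0.0], [1.0]])
        times = np.array([2.0, 1.0, 5.0, 3.0, 7.0, 4.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        m = CoxKPModel(standardize=False).fit(
            feature_matrix(X), CensoredSample(times, events)
        )
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [breslow_partial_loglik(np.array([b]), X, times, events) for b in grid]
        oracle = grid[int(np.argmax(lls))]
        assert m.beta_[0] == pytest.approx(oracle, abs=2e-4)

    def test_column_scaling_halves_coefficient(self, rng):
        X = rng.standard_normal((40, 1))
        times = rng.exponential(np.exp(-0.5 * X[:, 0]), 40) + 0.01
        y = CensoredSample(times, np.ones(40, dtype=int))
        b1 = CoxKPModel(standardize=False).fit(feature_matrix(X), y).beta_[0]
        b2 = CoxKPModel(standardize=False).fit(feature_matrix(2 * X), y).beta_[0]
        assert b2 == pytest.approx(b1 / 2, rel=1e-6)

    def test_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        X = rng.standard_normal((60, 3))
        times = rng.exponential(np.exp(-(0.4 * X[:, 0] - 0.3 * X[:, 2])), 60) + 0.01
        events = (rng.uniform(size=60) > 0.25).astype(int)
        events[0] = 1
        m = CoxKPModel(standardize=False).fit(feature_matrix(X), CensoredSample(times, events))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["t"], df["e"] = times, events
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(m.beta_, cph.params_.values, atol=1e-4)

    def test_predict_center_is_baseline(self, rng):
        y = random_censored_sample(rng, n=30)
        X = rng.standard_normal((30, 2))
        m = CoxKPModel().fit(feature_matrix(X), y)
        center = X.mean(axis=0)
        curve = m.predict_curves(center[None, :])[0]
        np.testing.assert_allclose(curve.knot_survival, m.baseline_.knot_survival)

    def test_higher_risk_lower_curve(self, rng):
        y = random_censored_sample(rng, n=50)
        X = rng.standard_normal((50, 2))
        m = CoxKPModel().fit(feature_matrix(X), y)
        # order two random patients by risk score and compare curves pointwise
        Z = (X - m.scaler_.mean_) / m.scaler_.scale_
        scores = Z @ m.beta_
        i, j = int(np.argmin(scores)), int(np.argmax(scores))
        lo, hi = m.predict_curves(X[[j, i]])
        assert np.all(lo.knot_survival <= hi.knot_survival + 1e-12)

    def test_feature_permutation_invariance(self, rng):
        y = random_censored_sample(rng, n=40)
        X = rng.standard_normal((40, 4))
        perm = np.array([2, 0, 3, 1])
        m1 = CoxKPModel().fit(feature_matrix(X), y)
        m2 = CoxKPModel().fit(feature_matrix(X[:, perm]), y)
        x_new = rng.standard_normal((3, 4))
        c1 = m1.predict_curves(x_new)
        c2 = m2.predict_curves(x_new[:, perm])
        for a, b in zip(c1, c2):
            np.testing.assert_allclose(a.knot_survival, b.knot_survival, atol=1e-8)

    def test_requires_event(self):
        with pytest.raises(ValueError):
            CoxKPModel().fit(
                feature_matrix(np.zeros((3, 1))), CensoredSample([1, 2, 3], [0, 0, 0])
            )

    def test_separation_raises(self):
        # perfectly separating covariate on untied data -> diverging beta
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        with pytest.raises(ConvergenceError):
            cox_newton(X, times, np.ones(6), ridge=0.0)

    def test_serialization_round_trip(self, rng, tmp_path):
        from alsurv.models import ISDModel

        y = random_censored_sample(rng, n=30)
        X = rng.standard_normal((30, 2))
        m = CoxKPModel().fit(feature_matrix(X), y)
        path = tmp_path / "cox.json"
        m.save(path)
        m2 = ISDModel.load(path)
        x_new = rng.standard_normal((2, 2))
        for a, b in zip(m.predict_curves(x_new), m2.predict_curves(x_new)):
            np.testing.assert_allclose(a.knot_survival, b.knot_survival)


class TestMTLR:
    def test_zero_features_identical_curves(self, rng):
        y = random_censored_sample(rng, n=40)
        X = feature_matrix(np.zeros((40, 3)))
        m = MTLRModel(l2_const=1.0).fit(X, y)
        curves = m.predict_curves(rng.standard_normal((5, 3)) * 0)
        base = curves[0].knot_survival
        for c in curves[1:]:
            np.testing.assert_allclose(c.knot_survival, base)

    def test_fully_regularized_limit_is_uniform(self, rng):
        y = random_censored_sample(rng, n=40, censor_rate=0.0)
        X = feature_matrix(rng.standard_normal((40, 3)))
        m = MTLRModel(l2_const=1e8).fit(X, y)
        curve = m.predict_curves(rng.standard_normal((1, 3)))[0]
        mg = m.fitted_grid_.m
        expected = [(mg + 1 - j) / (mg + 1) for j in range(mg + 1)]
        np.testing.assert_allclose(curve.knot_survival, expected, atol=1e-3)

    def test_optimum_beats_grid_search(self):
        # 1 feature, m = 2 bins, 4 patients: compare the optimized objective
        # against an exhaustive box search over (theta_1, theta_2, b_1, b_2)
        X = np.array([[-1.0], [0.5], [1.0], [-0.5]])
        y = CensoredSample([1.0, 4.0, 6.0, 2.0], [1, 1, 0, 1])
        grid = TimeGrid([2.5, 5.0])
        m = MTLRModel(l2_const=0.5, grid=grid, standardize=False).fit(
            feature_matrix(X), y
        )
        opt = np.concatenate([m.theta_.ravel(), m.bias_])
        from alsurv.models.mtlr import _censor_first_interval, _event_interval

        edges = grid.bin_edges
        kidx = np.where(
            y.events == 1,
            _event_interval(y.times, edges),
            _censor_first_interval(y.times, edges),
        )
        cmask = y.events == 0
        obj_opt, grad = _neg_log_posterior(opt, X, kidx, cmask, 0.5, 2, 1)
        assert np.max(np.abs(grad)) < 1e-3  # near-stationarity at the optimizer
        axis = np.arange(-2.0, 2.0 + 1e-9, 0.25)
        best = np.inf
        for t1 in axis:
            for t2 in axis:
                for b1 in axis:
                    for b2 in axis:
                        p = np.array([t1, t2, b1, b2])
                        o, _ = _neg_log_posterior(p, X, kidx, cmask, 0.5, 2, 1)
                        best = min(best, o)
        assert obj_opt <= best + 1e-9

    def test_sequence_probs_sum_to_one(self, rng):
        y = random_censored_sample(rng, n=25)
        X = feature_matrix(rng.standard_normal((25, 2)))
        m = MTLRModel(l2_const=1.0).fit(X, y)
        for _ in range(100):
            m.theta_ = rng.standard_normal(m.theta_.shape)
            m.bias_ = rng.standard_normal(m.bias_.shape)
            probs = m.predict_sequence_probs(rng.standard_normal((4, 2)))
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_curves_monotone_for_random_parameters(self, rng):
        y = random_censored_sample(rng, n=25)
        X = feature_matrix(rng.standard_normal((25, 2)))
        m = MTLRModel(l2_const=1.0).fit(X, y)
        for _ in range(100):
            m.theta_ = rng.standard_normal(m.theta_.shape) * 2
            m.bias_ = rng.standard_normal(m.bias_.shape) * 2
            assert_valid_curves(m.predict_curves(rng.standard_normal((3, 2))))

    def test_objective_monotone_across_iterations(self, rng):
        y = random_censored_sample(rng, n=60)
        X = feature_matrix(rng.standard_normal((60, 4)))
        m = MTLRModel(l2_const=0.1).fit(X, y)
        path = np.asarray(m.objective_path_)
        assert len(path) > 1
        assert np.all(np.diff(path) <= 1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        y = random_censored_sample(rng, n=20)
        m = MTLRModel().fit(feature_matrix(rng.standard_normal((20, 3))), y)
        with pytest.raises(ValueError):
            m.predict_curves(rng.standard_normal((2, 4)))

    def test_grid_default_square_root_rule(self, rng):
        times = rng.uniform(1, 50, 100)
        y = CensoredSample(times, np.ones(100, dtype=int))
        grid = TimeGrid.from_sample(y)
        assert grid.m == int(np.ceil(np.sqrt(100)))
        assert grid.bin_edges[-1] == pytest.approx(times.max())


class TestAFT:
    def test_lognormal_recovery_uncensored(self):
        sim = simulate_cohort(
            SimConfig(
                n_patients=2000, n_clinical=5, n_image=1, n_informative_clinical=3,
                missing_rate=0.0, target_censor_rate=0.01, seed=7,
            )
        )
        co = sim.cohort.restrict_block("clinical")
        m = AFTModel(standardize=False).fit(co.feature_matrix(), co.sample)
        truth = sim.truth["beta_clinical"]
        for j in range(5):
            assert abs(m.coef_[j] - truth[j]) < 3 * m.se_[j]

    def test_lognormal_recovery_with_censoring(self):
        sim = simulate_cohort(
            SimConfig(
                n_patients=2000, n_clinical=5, n_image=1, n_informative_clinical=3,
                missing_rate=0.0, target_censor_rate=0.30, seed=8,
            )
        )
        assert 0.2 < 1 - sim.cohort.events.mean() < 0.4
        co = sim.cohort.restrict_block("clinical")
        m = AFTModel(standardize=False).fit(co.feature_matrix(), co.sample)
        truth = sim.truth["beta_clinical"]
        for j in range(5):
            assert abs(m.coef_[j] - truth[j]) < 3 * m.se_[j]

    @pytest.mark.parametrize("family,censor", [("lognormal", 0.0), ("lognormal", 0.3),
                                               ("weibull", 0.3)])
    def test_matches_lifelines_aft(self, rng, family, censor):
        # independent cross-check of the censored MLE against lifelines
        import pandas as pd
        from lifelines import LogNormalAFTFitter, WeibullAFTFitter

        X = rng.standard_normal((300, 2))
        lin = 3.0 + 0.4 * X[:, 0] - 0.2 * X[:, 1]
        times = np.exp(lin + 0.5 * rng.standard_normal(300))
        events = (rng.uniform(size=300) > censor).astype(int)
        y = CensoredSample(times, events)
        m = AFTModel(family=family, standardize=False).fit(feature_matrix(X), y)
        df = pd.DataFrame(X, columns=["x0", "x1"])
        df["time"], df["event"] = times, events
        cls = LogNormalAFTFitter if family == "lognormal" else WeibullAFTFitter
        ll = cls().fit(df, duration_col="time", event_col="event")
        loc = ll.params_["mu_" if family == "lognormal" else "lambda_"]
        np.testing.assert_allclose(m.coef_, [loc["x0"], loc["x1"]], atol=2e-3)
        np.testing.assert_allclose(m.intercept_, loc["Intercept"], atol=2e-3)

    def test_intercept_only_lognormal_is_mean_log_time(self, rng):
        times = rng.lognormal(3.0, 0.5, 200)
        y = CensoredSample(times, np.ones(200, dtype=int))
        m = AFTModel().fit(feature_matrix(np.zeros((200, 0))), y)
        assert m.intercept_ == pytest.approx(np.mean(np.log(times)), abs=1e-4)

    def test_weibull_family(self, rng):
        y = random_censored_sample(rng, n=100, censor_rate=0.2)
        X = feature_matrix(rng.standard_normal((100, 2)))
        m = AFTModel(family="weibull").fit(X, y)
        assert_valid_curves(m.predict_curves(rng.standard_normal((3, 2))))

    def test_valid_curves_and_permutation_invariance(self, rng):
        y = random_censored_sample(rng, n=80)
        X = rng.standard_normal((80, 3))
        perm = np.array([1, 2, 0])
        m1 = AFTModel().fit(feature_matrix(X), y)
        m2 = AFTModel().fit(feature_matrix(X[:, perm]), y)
        x_new = rng.standard_normal((3, 3))
        c1, c2 = m1.predict_curves(x_new), m2.predict_curves(x_new[:, perm])
        assert_valid_curves(c1)
        for a, b in zip(c1, c2):
            np.testing.assert_allclose(a.knot_survival, b.knot_survival, atol=1e-6)

    def test_serialization_round_trip(self, rng, tmp_path):
        from alsurv.models import ISDModel

        y = random_censored_sample(rng, n=60)
        X = rng.standard_normal((60, 2))
        m = AFTModel().fit(feature_matrix(X), y)
        m.save(tmp_path / "aft.json")
        m2 = ISDModel.load(tmp_path / "aft.json")
        x_new = rng.standard_normal((2, 2))
        for a, b in zip(m.predict_curves(x_new), m2.predict_curves(x_new)):
            np.testing.assert_allclose(a.knot_survival, b.knot_survival)


class TestRSF:
    def test_single_leaf_equals_nelson_aalen_of_bootstrap(self, rng):
        y = random_censored_sample(rng, n=40)
        X = feature_matrix(rng.standard_normal((40, 3)))
        m = RSFModel(n_trees=1, max_depth=0, seed=5).fit(X, y)
        idx = m.bootstrap_indices_[0]
        expected = _na_survival(y.times[idx], y.events[idx], m.grid_)
        curve = m.predict_curves(rng.standard_normal((1, 3)))[0]
        np.testing.assert_allclose(curve.knot_survival[1:], expected)

    def test_separated_groups_first_split_on_signal(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            g = rng.integers(0, 2, 60)
            times = np.where(g == 1, rng.uniform(20, 40, 60), rng.uniform(1, 5, 60))
            X = np.column_stack([rng.standard_normal(60), g.astype(float),
                                 rng.standard_normal(60)])
            y = CensoredSample(times, np.ones(60, dtype=int))
            m = RSFModel(n_trees=1, mtry=3, max_depth=1, seed=seed).fit(
                feature_matrix(X), y
            )
            root = m.trees_[0]
            if "feature" in root and root["feature"] == 1:
                hits += 1
        assert hits >= 95

    def test_same_seed_identical_curves(self, rng):
        y = random_censored_sample(rng, n=50)
        X = rng.standard_normal((50, 4))
        x_new = rng.standard_normal((3, 4))
        c1 = RSFModel(n_trees=10, seed=3).fit(feature_matrix(X), y).predict_curves(x_new)
        c2 = RSFModel(n_trees=10, seed=3).fit(feature_matrix(X), y).predict_curves(x_new)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.knot_survival, b.knot_survival)

    def test_valid_curves(self, rng):
        y = random_censored_sample(rng, n=60)
        X = feature_matrix(rng.standard_normal((60, 5)))
        m = RSFModel(n_trees=20, seed=1).fit(X, y)
        assert_valid_curves(m.predict_curves(rng.standard_normal((5, 5))))

    def test_feature_permutation_invariance_full_mtry(self, rng):
        y = random_censored_sample(rng, n=50)
        X = rng.standard_normal((50, 3))
        perm = np.array([2, 0, 1])
        m1 = RSFModel(n_trees=5, mtry=3, seed=9).fit(feature_matrix(X), y)
        m2 = RSFModel(n_trees=5, mtry=3, seed=9).fit(feature_matrix(X[:, perm]), y)
        x_new = rng.standard_normal((3, 3))
        for a, b in zip(m1.predict_curves(x_new), m2.predict_curves(x_new[:, perm])):
            np.testing.assert_allclose(a.knot_survival, b.knot_survival)

    def test_serialization_round_trip(self, rng, tmp_path):
        from alsurv.models import ISDModel

        y = random_censored_sample(rng, n=40)
        X = rng.standard_normal((40, 3))
        m = RSFModel(n_trees=5, seed=2).fit(feature_matrix(X), y)
        m.save(tmp_path / "rsf.json")
        m2 = ISDModel.load(tmp_path / "rsf.json")
        x_new = rng.standard_normal((2, 3))
        for a, b in zip(m.predict_curves(x_new), m2.predict_curves(x_new)):
            np.testing.assert_array_equal(a.knot_survival, b.knot_survival)
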