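import numpy as np
import pandas as pd
import pytest

from deltarad.survival import (RiskModel, compute_rrs, concordance_index,
                               cox_fit, fit_lasso_cox, km_logrank,
                               stratify_by_cutoff)


def _clin(times, events):
    return pd.DataFrame({"os_months": times, "event": events})


def _sim(n, beta, rng, p_noise=20, censor=0.0):
    X = pd.DataFrame(rng.standard_normal((n, 3 + p_noise)),
                     columns=[f"pl{i}" for i in range(3)]
                     + [f"nz{i}" for i in range(p_noise)])
    lp = beta * X[["pl0", "pl1", "pl2"]].sum(axis=1)
    t = rng.exponential(1.0 / (0.05 * np.exp(lp)))
    e = np.ones(n, int)
    if censor:
        drop = rng.random(n) < censor
        t[drop] *= rng.random(drop.sum())
        e[drop] = 0
    return X, _clin(t, e)


class TestLassoCox:
    def test_huge_penalty_selects_nothing(self):
        rng = np.random.default_rng(0)
        X, clin = _sim(40, 1.0, rng)
        m = fit_lasso_cox(X, clin, lambda_grid=[1e4], n_folds=5, seed=0)
        assert m.features == []
        assert (compute_rrs(m, X) == 0).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        X, clin = _sim(60, 1.0, rng)
        m1 = fit_lasso_cox(X, clin, n_folds=5, seed=3)
        m2 = fit_lasso_cox(X, clin, n_folds=5, seed=3)
        assert m1.features == m2.features
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        assert m1.lambda_ == m2.lambda_

    def test_planted_features_recovered(self):
        rng = np.random.default_rng(2)
        X, clin = _sim(150, 1.5, rng, p_noise=50)
        m = fit_lasso_cox(X, clin, n_folds=5, seed=0)
        assert {"pl0", "pl1", "pl2"} <= set(m.features)

    def test_requires_events_and_cohort_size(self):
        rng = np.random.default_rng(3)
        X, clin = _sim(20, 0.0, rng)
        with pytest.raises(ValueError, match="10 patients"):
            fit_lasso_cox(X.iloc[:5], clin.iloc[:5])
        clin0 = clin.copy()
        clin0["event"] = 0
        with pytest.raises(ValueError, match="events"):
            fit_lasso_cox(X, clin0, n_folds=5)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X, clin = _sim(40, 1.0, rng)
        m = fit_lasso_cox(X, clin, n_folds=5, seed=0)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = RiskModel.from_json(path)
        assert back.features == m.features
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        assert back.rrs_cutoff == pytest.approx(m.rrs_cutoff)


class TestRRS:
    def test_linear_combination_example(self):
        m = RiskModel(["a", "b"], np.array([0.5, -0.3]), 0.1, np.array([0.1]),
                      np.array([0.0]), "deviance", 0.0)
        X = pd.DataFrame({"a": [2.0], "b": [1.0]})
        assert compute_rrs(m, X).iloc[0] == pytest.approx(0.7)
        assert compute_rrs(m, 2 * X).iloc[0] == pytest.approx(1.4)

    def test_missing_feature_raises(self):
        m = RiskModel(["a"], np.array([1.0]), 0.1, np.array([0.1]),
                      np.array([0.0]), "deviance", 0.0)
        with pytest.raises(ValueError, match="missing"):
            compute_rrs(m, pd.DataFrame({"b": [1.0]}))


class TestStratify:
    def test_median_split_with_tie_to_low(self):
        scores = np.array([-1.0, 0.0, 1.0, 2.0])
        cutoff = np.median(scores)       # 0.5
        assert list(stratify_by_cutoff(scores, cutoff)) == \
            ["low", "low", "high", "high"]
        assert stratify_by_cutoff([0.5], 0.5)[0] == "low"

    def test_validation_scored_against_training_cutoff(self):
        train = np.array([0.0, 1.0, 2.0, 3.0])
        cutoff = float(np.median(train))
        val = np.array([10.0, 11.0])     # own median irrelevant
        assert list(stratify_by_cutoff(val, cutoff)) == ["high", "high"]


class TestKaplanMeier:
    def test_hand_computed_product_limit_with_censoring(self):
        # events at 1,2,4,5,6; censored at 3
        clin = _clin([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1])
        res = km_logrank(np.repeat("all", 6), clin)
        curve = res.curves["all"].set_index("time")["survival"]
        expected = {1: 5 / 6, 2: 2 / 3, 4: 4 / 9, 5: 2 / 9, 6: 0.0}
        for t, s in expected.items():
            assert curve.loc[t] == pytest.approx(s)
        assert res.median_survival["all"] == pytest.approx(4.0)

    def test_uncensored_curve_drops_one_over_n(self):
        n = 5
        clin = _clin(np.arange(1, n + 1), np.ones(n, int))
        res = km_logrank(np.repeat("g", n), clin)
        surv = res.curves["g"]["survival"].to_numpy()
        assert surv[0] == 1.0                      # curve starts at 1 (t=0)
        np.testing.assert_allclose(surv[1:], 1 - np.arange(1, n + 1) / n)

    def test_identical_groups_give_null_logrank(self):
        clin = _clin([1, 2, 3, 4] * 2, [1, 1, 0, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = km_logrank(groups, clin)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.array([]), _clin([], []))


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(10)
        n = 500
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * 2.0 ** grp))
        fit = cox_fit(pd.DataFrame({"grp": grp}), _clin(t, np.ones(n, int)))
        hr = fit.summary["hr"].iloc[0]
        assert 1.7 <= hr <= 2.3

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(11)
        n = 600
        x = rng.standard_normal(n)
        t = rng.exponential(20.0, n)
        fit = cox_fit(pd.DataFrame({"x": x}), _clin(t, np.ones(n, int)))
        assert 0.8 <= fit.summary["hr"].iloc[0] <= 1.25

    def test_wald_p_close_to_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(12)
        n = 200
        grp = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * 1.4 ** grp))
        clin = _clin(t, np.ones(n, int))
        fit = cox_fit(pd.DataFrame({"grp": grp}), clin)
        km = km_logrank(np.where(grp == 1, "hi", "lo"), clin)
        assert fit.summary["p"].iloc[0] == pytest.approx(km.logrank_p, abs=0.03)

    def test_multivariable_needs_enough_events(self):
        clin = _clin([1, 2, 3], [1, 0, 0])
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="events"):
            cox_fit(X, clin, multivariable=True)


class TestConcordance:
    def test_perfect_ranking(self):
        clin = _clin([5, 4, 3, 2, 1], np.ones(5, int))
        scores = [1, 2, 3, 4, 5]   # higher score -> earlier death
        assert concordance_index(scores, clin) == 1.0

    def test_all_ties_give_half(self):
        clin = _clin([1, 2, 3, 4], np.ones(4, int))
        assert concordance_index(np.zeros(4), clin) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(13)
        n = 2000
        clin = _clin(rng.exponential(10, n), np.ones(n, int))
        c = concordance_index(rng.standard_normal(n), clin)
        assert abs(c - 0.5) < 0.05


def test_km_plot_export(tmp_path):
    clin = _clin([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1])
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    from deltarad.survival import plot_km

    res = km_logrank(groups, clin)
    out = tmp_path / "km.png"
    plot_km(res, out)
    assert out.stat().st_size > 0
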