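import numpy as np
import pandas as pd
import pytest

from deltarad.survival import concordance_index, cox_fit
from deltarad.utility import (assess_calibration, build_nomogram,
                              compare_clinical_groups, decision_curve,
                              horizon_outcomes, hosmer_lemeshow)


def _surv_frame(rng, n, beta=1.0, rate0=0.03):
    rrs = rng.standard_normal(n)
    t = rng.exponential(1.0 / (rate0 * np.exp(beta * rrs)))
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "os_months": t, "event": np.ones(n, int),
        "response": "responder", "age": rng.normal(60, 8, n),
        "race": rng.choice(["white", "black"], n),
        "baseline_tumor_volume_ml": rng.uniform(1, 10, n),
        "rrs": rrs,
    })


class TestDCA:
    def test_treat_none_identically_zero(self):
        rng = np.random.default_rng(0)
        dca = decision_curve(rng.random(50), rng.integers(0, 2, 50))
        assert (dca.curve["nb_none"] == 0).all()

    def test_treat_all_matches_closed_form(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        pi = y.mean()
        dca = decision_curve(rng.random(200), y)
        t = dca.curve["threshold"].to_numpy()
        np.testing.assert_allclose(dca.curve["nb_all"],
                                   pi - (1 - pi) * t / (1 - t))

    def test_perfect_predictor_net_benefit_equals_prevalence(self):
        y = np.array([0, 1, 1, 0, 1, 0, 0, 0])
        dca = decision_curve(y.astype(float), y)
        np.testing.assert_allclose(dca.curve["nb_model"], y.mean())

    def test_model_net_benefit_bounded_by_prevalence(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        dca = decision_curve(rng.random(300), y)
        assert (dca.curve["nb_model"] <= y.mean() + 1e-12).all()

    def test_thresholds_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[0.0, 0.5])


class TestGroupComparisons:
    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[3, 1], [1, 3]])
        res = compare_clinical_groups(table)
        # oracle: enumerate all tables with the same margins
        from math import comb

        row, col, n = table.sum(1), table.sum(0), table.sum()

        def prob(a):
            b, c = row[0] - a, col[0] - a
            d = row[1] - c
            if min(b, c, d) < 0:
                return 0.0
            return (comb(row[0], a) * comb(row[1], c)) / comb(n, col[0])

        p_obs = prob(table[0, 0])
        p_two = sum(prob(a) for a in range(col[0] + 1)
                    if prob(a) <= p_obs + 1e-12)
        assert res["p"] == pytest.approx(p_two)
        assert res["p"] == pytest.approx(0.4857, abs=1e-3)

    def test_identical_groups_t_statistic_zero(self):
        df = pd.DataFrame({
            "v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "g": ["a"] * 3 + ["b"] * 3,
        })
        res = compare_clinical_groups(df, "v", "g")
        assert res["test"] == "welch_t"
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            compare_clinical_groups(np.array([[0, 0], [2, 3]]))


class TestNomogram:
    def test_rrs_only_nomogram_matches_cox_c_index(self):
        rng = np.random.default_rng(3)
        df = _surv_frame(rng, 120)
        nomo = build_nomogram(df, df["rrs"], covariates=["rrs"])
        c_nomo = nomo.c_index(df, df)
        fit = cox_fit(df[["rrs"]], df)
        assert c_nomo == pytest.approx(fit.c_index, abs=1e-9)

    def test_predicted_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(4)
        df = _surv_frame(rng, 80)
        nomo = build_nomogram(df, df["rrs"])
        p = nomo.predict_survival(df)
        assert ((p > 0) & (p < 1)).all()

    def test_survival_monotone_decreasing_in_rrs(self):
        rng = np.random.default_rng(5)
        df = _surv_frame(rng, 100)
        nomo = build_nomogram(df, df["rrs"], covariates=["rrs"])
        probe = df.iloc[:1].copy()
        probs = []
        for r in (-2.0, 0.0, 2.0):
            probe["rrs"] = r
            probs.append(nomo.predict_survival(probe)[0])
        assert probs[0] > probs[1] > probs[2]

    def test_points_invariant_to_affine_covariate_rescaling(self):
        rng = np.random.default_rng(6)
        df = _surv_frame(rng, 100)
        nomo1 = build_nomogram(df, df["rrs"], covariates=["rrs", "age"])
        df2 = df.copy()
        df2["age"] = df2["age"] * 10 + 3
        nomo2 = build_nomogram(df2, df2["rrs"], covariates=["rrs", "age"])
        np.testing.assert_allclose(nomo1.total_points(df),
                                   nomo2.total_points(df2), rtol=1e-4)


class TestCalibration:
    def test_well_specified_model_passes_hosmer_lemeshow(self):
        hits = 0
        for r in range(10):
            rng = np.random.default_rng(100 + r)
            df = _surv_frame(rng, 250)
            nomo = build_nomogram(df, df["rrs"], covariates=["rrs"])
            pred = 1.0 - nomo.predict_survival(df)
            _, p, _ = hosmer_lemeshow(pred, df["os_months"], df["event"],
                                      nomo.horizon)
            hits += p > 0.05
        assert hits >= 8

    def test_squared_probabilities_fail_hosmer_lemeshow(self):
        hits = 0
        for r in range(5):
            rng = np.random.default_rng(200 + r)
            df = _surv_frame(rng, 250)
            nomo = build_nomogram(df, df["rrs"], covariates=["rrs"])
            pred = (1.0 - nomo.predict_survival(df)) ** 2
            _, p, _ = hosmer_lemeshow(pred, df["os_months"], df["event"],
                                      nomo.horizon)
            hits += p < 0.05
        assert hits >= 4

    def test_bootstrap_trace_length_matches_n_boot(self):
        rng = np.random.default_rng(7)
        df = _surv_frame(rng, 60)
        nomo = build_nomogram(df, df["rrs"], covariates=["rrs"])
        res = assess_calibration(nomo, df, n_boot=23, groups=5, seed=0)
        assert len(res.bootstrap_trace) == 23
        assert np.isfinite(res.c_index_corrected)
        assert res.c_index_corrected == pytest.approx(
            res.c_index_apparent - res.optimism)


def test_horizon_outcomes_excludes_early_censoring():
    clin = pd.DataFrame({
        "os_months": [10.0, 40.0, 20.0, 50.0],
        "event": [0, 0, 1, 1],
    })
    y, mask = horizon_outcomes(clin, 36.0)
    np.testing.assert_array_equal(mask, [False, True, True, True])
    np.testing.assert_array_equal(y, [0, 1, 0])


def test_decision_curve_plot_export(tmp_path):
    from deltarad.utility import plot_decision_curve

    rng = np.random.default_rng(8)
    dca = decision_curve(rng.random(60), rng.integers(0, 2, 60))
    out = tmp_path / "dca.png"
    plot_decision_curve(dca, out)
    assert out.stat().st_size > 0
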