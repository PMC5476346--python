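"""Estimators vs closed-form / brute-force oracles, and the model battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurochron.stats import (fisher_exact, linear_model, logistic_model,
                              one_sample_t, ordinal_logistic, pearson_cor,
                              run_cohort_models, two_sample_t)


class TestLinearModel:
    def test_binary_predictor_equals_group_mean_difference(self, rng):
        g = np.repeat([0.0, 1.0], [10, 12])
        y = rng.normal(0, 3, 22) + 5 * g
        res = linear_model(y, pd.DataFrame({"g": g}))
        m1, m0 = y[g == 1].mean(), y[g == 0].mean()
        assert res.term("g")["estimate"] == pytest.approx(m1 - m0, abs=1e-12)

    def test_group_means_reproduce_reported_contrast(self):
        """Group means +2.49 and -5.20 give a group coefficient of 7.69."""
        y = np.concatenate([np.array([1.0, 2.0, 4.47]) + 0.0,   # mean 2.49
                            np.array([-4.0, -5.0, -6.6])])      # mean -5.20
        g = np.repeat([1.0, 0.0], 3)
        assert y[:3].mean() == pytest.approx(2.49)
        assert y[3:].mean() == pytest.approx(-5.20)
        res = linear_model(y, pd.DataFrame({"group_ds": g}))
        assert res.term("group_ds")["estimate"] == pytest.approx(7.69)

    def test_normal_equations_oracle(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=6), "b": rng.normal(size=6)})
        y = rng.normal(size=6)
        res = linear_model(y, X)
        Xm = np.column_stack([np.ones(6), X["a"], X["b"]])
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        np.testing.assert_allclose(res.terms["estimate"], beta, atol=1e-10)
        # Wald machinery against the textbook formulas
        resid = y - Xm @ beta
        s2 = resid @ resid / (6 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xm.T @ Xm)))
        np.testing.assert_allclose(res.terms["se"], se, atol=1e-10)
        tcrit = sps.t.ppf(0.975, 3)
        np.testing.assert_allclose(res.terms["ci_high"], beta + tcrit * se,
                                   atol=1e-8)

    def test_collinear_design_rejected(self, rng):
        a = rng.normal(size=8)
        with pytest.raises(ValueError, match="collinear"):
            linear_model(rng.normal(size=8),
                         pd.DataFrame({"a": a, "a_dup": a}))


class TestLogisticModel:
    def test_intercept_only_quarter_positive(self):
        y = np.array([1.0] + [0.0] * 3)
        y = np.tile(y, 5)
        res = logistic_model(y, pd.DataFrame(index=range(20)))
        assert res.term("intercept")["estimate"] == pytest.approx(
            np.log(1 / 3), abs=1e-6)

    def test_newton_raphson_oracle(self):
        # fixed overlapping data: no separation, so Newton converges
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.2, 0.5, 1.0, 1.5, 2.0, -1.5])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        res = logistic_model(y, pd.DataFrame({"x": x}))
        X = np.column_stack([np.ones(10), x])
        beta = np.zeros(2)
        for _ in range(50):
            p = 1 / (1 + np.exp(-X @ beta))
            W = p * (1 - p)
            step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        np.testing.assert_allclose(res.terms["estimate"], beta, atol=1e-8)

    def test_label_flip_negates_coefficients(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.5).astype(float)
        r1 = logistic_model(y, pd.DataFrame({"x": x}))
        r2 = logistic_model(1 - y, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(r2.terms["estimate"],
                                   -r1.terms["estimate"], atol=1e-6)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_model(np.array([0.0, 1.0, 2.0]),
                           pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


class TestOrdinalLogistic:
    def test_two_levels_collapse_to_logistic(self, rng):
        x = rng.normal(size=40)
        y = (rng.random(40) < 1 / (1 + np.exp(-(0.8 * x)))).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        ores = ordinal_logistic(y, pd.DataFrame({"x": x}))
        lres = logistic_model(y.astype(float), pd.DataFrame({"x": x}))
        assert ores.term("x")["estimate"] == pytest.approx(
            lres.term("x")["estimate"], abs=1e-5)

    def test_proportional_odds_recovery(self):
        rng = np.random.default_rng(42)
        n, beta = 500, 1.0
        x = rng.normal(size=n)
        u = rng.logistic(size=n)
        latent = beta * x + u
        y = np.digitize(latent, [-1.0, 1.0])      # 3 ordered levels
        res = ordinal_logistic(y, pd.DataFrame({"x": x}))
        t = res.term("x")
        assert abs(t["estimate"] - beta) < 2 * t["se"]

    def test_thresholds_strictly_increasing(self, default_cohort_tables):
        ds = default_cohort_tables.cohort.query("group == 'DS'")
        res = ordinal_logistic(ds["camdex_class"],
                               pd.DataFrame({"x": ds["age_years"]}),
                               levels=["stable", "declining", "dementia"])
        cuts = res.terms[res.terms["term"].str.contains("/")]
        # statsmodels reports the first threshold and log-increments
        first = cuts["estimate"].iloc[0]
        second = first + np.exp(cuts["estimate"].iloc[1])
        assert second > first

    def test_empty_level_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ordinal_logistic(["a", "a", "b"], pd.DataFrame({"x": [1., 2., 3.]}),
                             levels=["a", "b", "c"])


class TestSimpleTests:
    def test_identical_groups_t_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        out = two_sample_t(g, g)
        assert out["statistic"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_welch_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0])
        out = two_sample_t(a, b)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert out["statistic"] == pytest.approx(t, abs=1e-12)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=9)
        assert two_sample_t(7 * a, 7 * b)["statistic"] == pytest.approx(
            two_sample_t(a, b)["statistic"])

    def test_one_sample_reference_equality(self):
        assert one_sample_t([2.0, 4.0, 6.0], 4.0)["statistic"] == 0.0

    def test_one_sample_hand_case_and_reflection(self):
        v = np.array([51.0, 48.0, 55.0, 47.0, 50.0])
        out = one_sample_t(v, 49.0)
        t = (v.mean() - 49.0) / (v.std(ddof=1) / np.sqrt(5))
        assert out["statistic"] == pytest.approx(t, abs=1e-12)
        reflected = one_sample_t(2 * 49.0 - v, 49.0)
        assert reflected["statistic"] == pytest.approx(-out["statistic"])

    def test_pearson_extremes_and_oracle(self, rng):
        x = rng.normal(size=12)
        assert pearson_cor(x, x)["r"] == pytest.approx(1.0)
        assert pearson_cor(x, -x)["r"] == pytest.approx(-1.0)
        y = rng.normal(size=12)
        out = pearson_cor(x, y)
        sx, sy = x - x.mean(), y - y.mean()
        r = np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2))
        assert out["r"] == pytest.approx(r, abs=1e-12)

    def test_fisher_balanced_table(self):
        out = fisher_exact([[5, 5], [5, 5]])
        assert out["p"] == pytest.approx(1.0)
        assert out["odds_ratio"] == pytest.approx(1.0)

    def test_fisher_hypergeometric_enumeration_oracle(self):
        table = np.array([[10, 0], [0, 10]])
        out = fisher_exact(table)
        # enumerate all tables with the same margins; two-sided point method
        n = 20
        r1 = c1 = 10
        p_obs = sps.hypergeom.pmf(10, n, r1, c1)
        total = sum(sps.hypergeom.pmf(k, n, r1, c1)
                    for k in range(0, 11)
                    if sps.hypergeom.pmf(k, n, r1, c1) <= p_obs * (1 + 1e-12))
        assert out["p"] == pytest.approx(total, rel=1e-10)

    def test_fisher_odds_ratio_identity(self):
        out = fisher_exact([[3, 4], [5, 6]])
        assert out["odds_ratio"] == pytest.approx(3 * 6 / (4 * 5))

    def test_fisher_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])


def _analysis_table(seed=0, interaction_slope=1.75, n_ds=46):
    """Merged analysis table from the generator (imaging-free shortcut:
    measured brain-PAD = true brain-PAD plus small measurement noise)."""
    from neurochron.amyloid import build_profiles
    from neurochron.synthetic import SimulationConfig, generate_cohort

    cfg = SimulationConfig(seed=seed, n_train=1, n_ds=n_ds,
                           camcog_interaction_slope=interaction_slope)
    data = generate_cohort(cfg, include_maps=False, include_tacs=False)
    coh = data.cohort[data.cohort["group"] != "train"].reset_index(drop=True)
    rng = np.random.default_rng(seed + 1)
    coh["brain_pad"] = coh["brain_pad_true"] + rng.normal(0, 3.0, len(coh))
    coh["icv_l"] = np.where(coh["group"] == "DS",
                            rng.normal(1.19, 0.11, len(coh)),
                            rng.normal(1.42, 0.14, len(coh)))
    prof = build_profiles(data.regional_truth)
    merged = coh.merge(prof, on="subject_id", how="left")
    return merged


class TestModelBattery:
    def test_twelve_documented_models(self):
        models = run_cohort_models(_analysis_table())
        assert [m.model_name for m in models] == [
            "brainpad_group", "icv_group", "pib_status_logistic",
            "mean_cortical_bpnd_linear", "abnormal_count_linear",
            "camcog_brainpad", "camcog_interaction", "camdex_ordinal",
            "camcog_bpnd_brainpad", "brainpad_group_stable",
            "cor_brainpad_icv", "ttests"]

    def test_missing_column_named(self):
        tbl = _analysis_table().drop(columns=["icv_l"])
        with pytest.raises(ValueError, match="icv_l"):
            run_cohort_models(tbl)

    def test_group_effect_recovers_offset(self):
        models = run_cohort_models(_analysis_table(seed=3))
        t = models[0].term("group_ds")
        assert abs(t["estimate"] - 8.0) < 3 * t["se"]

    # replicate seeds spaced beyond the generator's per-subject seed span
    # (seed + index) so replicates are independent

    def test_interaction_recovered_with_negative_sign(self):
        hits = 0
        for rep in range(10):
            models = run_cohort_models(_analysis_table(seed=100 + rep * 350_003))
            t = models[6].term("brain_pad_x_pib")
            hits += int(t["estimate"] < 0 and t["p"] < 0.05)
        assert hits >= 8

    def test_interaction_null_calibration(self):
        rejections = []
        for rep in range(100):
            models = run_cohort_models(
                _analysis_table(seed=500 + rep * 350_003,
                                interaction_slope=0.0))
            rejections.append(models[6].term("brain_pad_x_pib")["p"] < 0.05)
        assert np.mean(rejections) <= 0.12   # 95% binomial band around 0.05
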