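"""Synthetic cohort generator: determinism, structure, ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from neurochron.kinetics import TAC, frame_average
from neurochron.synthetic import (ConfigError, SimulationConfig,
                                  gamma_variate, generate_cohort,
                                  simulate_reference_tac,
                                  simulate_target_tac, simulate_tissue_maps)


class TestConfig:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_ds=0), "n_ds"),
        (dict(age_range_test=(60.0, 60.0)), "age_range_test"),
        (dict(grid_dims=(3, 8, 8)), "grid_dims"),
        (dict(pib_pos_fraction=1.5), "pib_pos_fraction"),
        (dict(atrophy_rate=0.02), "atrophy_rate"),      # 0.02 * 90 > 1
        (dict(peak_time_s=-5.0), "peak_time"),
        (dict(tac_noise_cv=-0.1), "tac_noise_cv"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**kwargs).validate()


class TestDeterminism:
    def test_identical_outputs_for_same_seed(self):
        cfg = SimulationConfig(n_train=5, n_ds=6, n_control=4, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.cohort, b.cohort)
        for sid in a.maps:
            np.testing.assert_array_equal(a.maps[sid].gm, b.maps[sid].gm)
        for sid in a.tacs:
            pd.testing.assert_frame_equal(a.tacs[sid], b.tacs[sid])

    def test_adding_subjects_preserves_earlier_draws(self):
        small = generate_cohort(SimulationConfig(n_train=4, n_ds=3,
                                                 n_control=2, seed=9),
                                include_maps=False, include_tacs=False)
        # same train prefix, more DS subjects appended after them
        big = generate_cohort(SimulationConfig(n_train=4, n_ds=5,
                                               n_control=2, seed=9),
                              include_maps=False, include_tacs=False)
        cols = ["subject_id", "age_years", "sex", "group"]
        pd.testing.assert_frame_equal(
            small.cohort.loc[:6, cols], big.cohort.loc[:6, cols])


class TestCohortStructure:
    def test_reported_cohort_sizes(self, default_cohort_tables):
        coh = default_cohort_tables.cohort
        test = coh[coh["group"] != "train"]
        assert len(test) == 76
        assert (coh["group"] == "DS").sum() == 46
        assert (coh["group"] == "control").sum() == 30

    def test_missing_camcog_occurs_only_in_ds(self, default_cohort_tables):
        coh = default_cohort_tables.cohort
        ds = coh[coh["group"] == "DS"]
        assert ds["camcog"].isna().any()
        assert coh.loc[coh["group"] == "control", "camcog"].isna().all()

    def test_striatal_mixture_is_bimodal(self):
        cfg = SimulationConfig()
        pooled = np.sqrt(0.5 * (cfg.bpnd_neg_sd**2 + cfg.bpnd_pos_sd**2))
        assert (cfg.bpnd_pos_mean - cfg.bpnd_neg_mean) / pooled >= 4.0

    def test_null_offset_equalises_gm_age_slopes(self):
        """With group_offset = 0 the DS and control GM-volume age slopes
        agree (both estimate -atrophy_rate x pattern mass)."""
        cfg = SimulationConfig(n_train=1, n_ds=150, n_control=150, seed=31,
                               group_offset_years=0.0, pad_sd_years=0.0)
        data = generate_cohort(cfg, include_tacs=False)
        coh = data.cohort
        slopes = {}
        ses = {}
        for grp in ("DS", "control"):
            sub = coh[coh["group"] == grp]
            gm = np.array([data.maps[s].gm.sum() for s in sub["subject_id"]])
            age = sub["age_years"].to_numpy()
            A = np.column_stack([np.ones(len(sub)), age])
            beta, res_, *_ = np.linalg.lstsq(A, gm, rcond=None)
            resid = gm - A @ beta
            s2 = resid @ resid / (len(sub) - 2)
            ses[grp] = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
            slopes[grp] = beta[1]
        diff_se = np.hypot(ses["DS"], ses["control"])
        assert abs(slopes["DS"] - slopes["control"]) < 2 * diff_se


class TestTissueMaps:
    def test_zero_atrophy_and_noise_age_independent(self):
        cfg = SimulationConfig(atrophy_rate=0.0, feature_noise_sd=0.0)
        m1 = simulate_tissue_maps(20.0, cfg)
        m2 = simulate_tissue_maps(80.0, cfg)
        np.testing.assert_array_equal(m1.gm, m2.gm)

    def test_monotone_atrophy(self):
        cfg = SimulationConfig(feature_noise_sd=0.0)
        young = simulate_tissue_maps(18.0, cfg)
        old = simulate_tissue_maps(90.0, cfg)
        assert old.gm.mean() < young.gm.mean()

    def test_probabilities_sum_to_at_most_one(self):
        """Exhaustive voxel scan over 100 random subjects."""
        cfg = SimulationConfig(seed=5)
        rng = np.random.default_rng(5)
        for _ in range(100):
            age = rng.uniform(18, 95)
            m = simulate_tissue_maps(age, cfg, rng,
                                     csf_scale=rng.uniform(0.3, 1.0))
            total = m.gm + m.wm + m.csf
            assert total.min() >= 0.0
            assert total.max() <= 1.0 + 1e-9

    def test_age_slope_recovery_in_controls(self):
        """GM volume regressed on age recovers -atrophy_rate x pattern mass
        within 2 SE at n = 200."""
        cfg = SimulationConfig(seed=13)
        rng = np.random.default_rng(13)
        ages = rng.uniform(20, 80, 200)
        gm = np.array([simulate_tissue_maps(a, cfg, rng).gm.sum()
                       for a in ages])
        A = np.column_stack([np.ones(200), ages])
        beta, *_ = np.linalg.lstsq(A, gm, rcond=None)
        resid = gm - A @ beta
        se = np.sqrt((resid @ resid / 198) * np.linalg.inv(A.T @ A)[1, 1])
        from neurochron.synthetic import _spatial_fields
        _, _, pattern, _ = _spatial_fields(cfg.grid_dims, cfg.voxel_size_mm)
        expected = -cfg.atrophy_rate * pattern.sum()
        assert abs(beta[1] - expected) < 2 * se


class TestReferenceCurve:
    def test_peak_value_equals_scale(self, schedule):
        t = schedule.fine_times(1.0)
        curve = gamma_variate(t, 300.0, scale=7.5)
        assert curve[t == 300.0][0] == pytest.approx(7.5)
        assert curve[0] == 0.0
        assert (curve >= 0).all()

    def test_invalid_peak_time(self, schedule):
        with pytest.raises(ValueError):
            simulate_reference_tac(schedule, peak_time_s=0.0)


class TestTargetTac:
    def test_unit_r1_zero_binding_equals_reference(self, schedule,
                                                   reference_curve):
        ref_tac, ft, fv = reference_curve
        tac = simulate_target_tac(fv, ft, 1.0, 0.15, 0.0, schedule,
                                  noise_cv=0.0)
        np.testing.assert_allclose(tac.activity, ref_tac.activity, atol=1e-9)

    def test_zero_r1_vanishing_k2_gives_zero(self, schedule, reference_curve):
        _, ft, fv = reference_curve
        tac = simulate_target_tac(fv, ft, 0.0, 1e-12, 0.3, schedule,
                                  noise_cv=0.0)
        assert np.max(np.abs(tac.activity)) < 1e-9

    def test_negative_bpnd_rejected(self, schedule, reference_curve):
        _, ft, fv = reference_curve
        with pytest.raises(ValueError):
            simulate_target_tac(fv, ft, 1.0, 0.15, -0.2, schedule)

    def test_noiseless_matches_analytic_single_exponential(self, schedule):
        """Forward frame values vs the closed-form convolution for an
        exponential reference curve."""
        ft = schedule.fine_times(0.5)
        lam = 0.004
        fv = np.exp(-lam * ft)
        r1, k2, bp = 1.1, 0.12, 0.6
        k2a = k2 / (1 + bp) / 60.0
        th2 = (k2 - r1 * k2 / (1 + bp)) / 60.0
        analytic = r1 * fv + th2 * (np.exp(-k2a * ft) - np.exp(-lam * ft)) / (
            lam - k2a)
        expected = frame_average(analytic, ft, schedule)
        tac = simulate_target_tac(fv, ft, r1, k2, bp, schedule, noise_cv=0.0)
        np.testing.assert_allclose(tac.activity, expected, rtol=1e-3)


class TestKineticGroundTruth:
    def test_fitted_bpnd_tracks_generated_truth(self):
        """End-to-end: generated noisy TACs refit with the basis method
        correlate strongly with the generating BP_ND values."""
        from neurochron.kinetics import srtm_basis_fit

        cfg = SimulationConfig(n_train=1, n_ds=4, n_control=1, seed=17)
        data = generate_cohort(cfg, include_maps=False)
        truths, fits = [], []
        for sid, table in data.tacs.items():
            sched = data.schedule
            ref = TAC(sched, table["superior_cerebellum"].to_numpy())
            for roi in ("putamen_l", "frontal_l", "temporal_r"):
                tac = TAC(sched, table[roi].to_numpy())
                fit = srtm_basis_fit(tac, ref)
                truths.append(data.regional_truth.loc[sid, roi])
                fits.append(fit.bpnd)
        truths, fits = np.array(truths), np.array(fits)
        assert np.corrcoef(truths, fits)[0, 1] > 0.95
        assert np.median(np.abs(fits - truths)) < 0.1
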