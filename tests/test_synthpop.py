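"""Cohort generator: determinism, calibration, identities, missingness, split."""

import numpy as np
import pandas as pd
import pytest

from dmscreen.cascade import DiagnosticThresholds
from dmscreen.synthpop import (
    CalibrationError,
    ConfigError,
    calibrate_generator,
    default_config,
    inject_missingness,
    sample_population,
    split_dev_test,
)


class TestSamplePopulation:
    def test_same_seed_gives_bit_identical_tables(self):
        cfg = default_config(n_participants=500, seed=99)
        pd.testing.assert_frame_equal(sample_population(cfg), sample_population(cfg))

    def test_different_seed_differs(self):
        a = sample_population(default_config(n_participants=500, seed=1))
        b = sample_population(default_config(n_participants=500, seed=2))
        assert not a["fpg"].equals(b["fpg"])

    def test_row_count_and_schema(self):
        pop = sample_population(default_config(n_participants=123, seed=0))
        assert len(pop) == 123
        for col in ("person_id", "age", "fpg", "p2hpg", "hba1c", "bmi",
                    "dm_status", "subtype"):
            assert col in pop.columns

    def test_empty_cohort_keeps_full_schema(self):
        empty = sample_population(default_config(n_participants=0, seed=0))
        nonempty = sample_population(default_config(n_participants=5, seed=0))
        assert len(empty) == 0
        assert list(empty.columns) == list(nonempty.columns)

    def test_realized_prevalence_near_target(self, big_cohort):
        prev = big_cohort["dm_status"].mean()
        se = np.sqrt(0.124 * 0.876 / len(big_cohort))
        assert abs(prev - 0.124) < 3 * se

    def test_non_dm_feature_medians_match_baselines(self, big_cohort):
        cfg = default_config()
        non = big_cohort[~big_cohort["dm_status"]]
        for feat, (median, _) in cfg.feature_baselines.items():
            assert non[feat].median() == pytest.approx(median, rel=0.05), feat

    def test_anthropometric_identities_hold_rowwise(self, small_cohort):
        pop = small_cohort
        np.testing.assert_allclose(pop["bmi"], pop["weight"] / pop["height"] ** 2,
                                   atol=1e-6)
        np.testing.assert_allclose(pop["whr"], pop["wc"] / pop["hc"], atol=1e-6)
        np.testing.assert_allclose(pop["whtr"], pop["wc"] / (pop["height"] * 100),
                                   atol=1e-6)

    def test_labs_strictly_positive(self, small_cohort):
        assert (small_cohort[["fpg", "p2hpg", "hba1c"]] > 0).all().all()

    def test_status_consistent_with_diagnostic_rule(self, small_cohort):
        thr = DiagnosticThresholds()
        expect = (small_cohort["fpg"] >= thr.fpg_dm) | (small_cohort["p2hpg"] >= thr.p2hpg_dm)
        assert (small_cohort["dm_status"] == expect).all()
        assert ((small_cohort["subtype"] != "NON_DM") == expect).all()

    def test_zero_loadings_give_equal_group_medians(self):
        cfg = default_config(n_participants=50_000, seed=3)
        cfg.latent_loading_per_feature = {f: 0.0 for f in cfg.latent_loading_per_feature}
        cfg.glucose_model.z_share_fpg = 1e-9
        cfg.glucose_model.z_share_p2hpg = 1e-9
        # keep the marginal glucose correlation as calibrated
        cfg = calibrate_generator(cfg, verify=False)
        pop = sample_population(cfg)
        dm, non = pop[pop["dm_status"]], pop[~pop["dm_status"]]
        for feat in ("age", "rpr", "sbp", "wc"):
            lo, hi = np.percentile(non[feat], [45, 55])  # Monte-Carlo band
            assert lo < dm[feat].median() < hi, feat

    def test_invalid_configs_name_the_field(self):
        cfg = default_config(n_participants=10)
        cfg.target_subtype_fractions = (0.5, 0.4, 0.2)
        with pytest.raises(ConfigError, match="subtype_fractions"):
            sample_population(cfg)
        cfg2 = default_config(n_participants=10)
        cfg2.glucose_model.log_sd_fpg = -1.0
        with pytest.raises(ConfigError, match="SD"):
            sample_population(cfg2)
        cfg3 = default_config(n_participants=10)
        cfg3.missingness_rate = 0.25
        with pytest.raises(ConfigError, match="missing"):
            sample_population(cfg3)


class TestCalibration:
    def test_default_calibration_hits_prevalence_and_subtypes(self, big_cohort):
        prev = big_cohort["dm_status"].mean()
        assert abs(prev - 0.124) < 0.01
        dm = big_cohort[big_cohort["dm_status"]]
        fr = {s: (dm["subtype"] == s).mean()
              for s in ("ISOLATED_POSTLOAD", "ISOLATED_FASTING", "COMBINED")}
        assert fr["ISOLATED_POSTLOAD"] == pytest.approx(0.41, abs=0.03)
        assert fr["ISOLATED_FASTING"] == pytest.approx(0.28, abs=0.03)
        assert fr["COMBINED"] == pytest.approx(0.31, abs=0.03)

    def test_fixed_point_returns_equivalent_config(self):
        cfg = default_config()
        again = calibrate_generator(cfg, verify=False)
        g0, g1 = cfg.glucose_model, again.glucose_model
        assert g1.log_sd_fpg == pytest.approx(g0.log_sd_fpg, abs=1e-12)
        assert g1.residual_rho == pytest.approx(g0.residual_rho, abs=1e-12)

    def test_calibration_matches_grid_search_oracle(self):
        """The solved total correlation agrees with a brute-force grid scan
        of the bivariate-normal orthant probability."""
        from scipy.stats import multivariate_normal, norm

        cfg = calibrate_generator(default_config(), verify=False)
        g = cfg.glucose_model
        q1 = (np.log(7.0) - g.log_median_fpg) / g.log_sd_fpg
        q2 = (np.log(11.1) - g.log_median_p2hpg) / g.log_sd_p2hpg
        grid = np.linspace(-0.99, 0.99, 397)
        probs = [multivariate_normal.cdf([q1, q2], cov=[[1, r], [r, 1]]) for r in grid]
        best = grid[np.argmin(np.abs(np.array(probs) - (1 - 0.124)))]
        assert g.total_rho == pytest.approx(best, abs=0.01)

    def test_infeasible_targets_raise_with_diagnostics(self):
        cfg = default_config()
        with pytest.raises((CalibrationError, ConfigError)):
            calibrate_generator(cfg, targets={"prevalence": 0.124,
                                              "subtype_fractions": (0.0, 0.0, 1.0)},
                                verify=False)

    def test_sampled_verification_passes_for_the_solved_model(self):
        calibrate_generator(default_config(), verify=True, n_calibration=20_000)

    def test_median_above_threshold_is_rejected(self):
        cfg = default_config()
        cfg.glucose_model.log_median_fpg = np.log(7.5)  # above the diagnostic cut
        with pytest.raises(CalibrationError, match="cannot calibrate"):
            calibrate_generator(cfg, verify=False)

    def test_mean_shift_monotone_in_prevalence(self):
        cfg = calibrate_generator(default_config(), verify=False)
        prevs = []
        for shift in (-0.05, 0.0, 0.05):
            c = calibrate_generator(default_config(), verify=False)
            c.glucose_model.log_median_fpg += shift
            c.glucose_model.log_median_p2hpg += shift
            c.n_participants, c.seed = 50_000, 17
            prevs.append(sample_population(c)["dm_status"].mean())
        assert prevs[0] < prevs[1] < prevs[2]


class TestMissingness:
    def test_rate_zero_is_identity(self, small_cohort):
        pd.testing.assert_frame_equal(inject_missingness(small_cohort, 0.0, seed=1),
                                      small_cohort)

    def test_per_column_missing_fraction_within_binomial_band(self):
        pop = sample_population(default_config(n_participants=10_000, seed=21))
        out = inject_missingness(pop, 0.10, seed=2)
        for col in ("age", "rpr", "sex", "sbp"):
            assert 0.09 <= out[col].isna().mean() <= 0.11, col

    def test_labs_and_outcomes_never_masked(self):
        pop = sample_population(default_config(n_participants=2_000, seed=22))
        out = inject_missingness(pop, 0.19, seed=3)
        for col in ("fpg", "p2hpg", "hba1c", "dm_status", "subtype", "person_id"):
            assert out[col].notna().all(), col

    def test_rate_at_exclusion_boundary_rejected(self, small_cohort):
        with pytest.raises(ConfigError, match="20%"):
            inject_missingness(small_cohort, 0.25, seed=1)
        with pytest.raises(ConfigError):
            inject_missingness(small_cohort, 0.20, seed=1)

    def test_reproducible_by_seed(self, small_cohort):
        a = inject_missingness(small_cohort, 0.1, seed=9)
        b = inject_missingness(small_cohort, 0.1, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSplit:
    def test_sizes_forced_by_rounding(self):
        pop = sample_population(default_config(n_participants=8425, seed=4))
        dev, test = split_dev_test(pop, 0.6, seed=1)
        assert (len(dev), len(test)) == (5055, 3370)

    def test_partition_disjoint_and_exhaustive(self, small_cohort):
        dev, test = split_dev_test(small_cohort, 0.6, seed=2)
        ids = pd.concat([dev["person_id"], test["person_id"]])
        assert ids.is_unique and len(ids) == len(small_cohort)

    def test_two_rows_split_one_one(self, small_cohort):
        dev, test = split_dev_test(small_cohort.head(2), 0.5, seed=0)
        assert (len(dev), len(test)) == (1, 1)

    def test_same_seed_same_membership(self, small_cohort):
        a = split_dev_test(small_cohort, 0.6, seed=7)[0]
        b = split_dev_test(small_cohort, 0.6, seed=7)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_inputs_rejected(self, small_cohort):
        with pytest.raises(ConfigError):
            split_dev_test(small_cohort.head(1), 0.6, seed=0)
        with pytest.raises(ConfigError):
            split_dev_test(small_cohort, 1.0, seed=0)
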