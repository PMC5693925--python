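"""Group-level statistics: mixed models, correlations, t-tests, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nirsflow.cohort import CohortConfig, GASlopes, SexEffects, simulate_cohort
from nirsflow.stats import (
    DegenerateDesignError,
    aggregate_repetitions,
    demographics_ttest,
    lme_ga_trend,
    lme_sex_contrast,
    pearson_ga,
    percent_side_difference,
)

from conftest import zero_noise, zero_variability


def truth_cohort(cfg):
    raw = simulate_cohort(cfg, emit_raw=False)
    return aggregate_repetitions(raw.measurements), raw.subjects


class TestAggregation:
    def test_single_repetition_passthrough(self):
        df = pd.DataFrame({"subject_id": ["a"], "location": ["frontal_left"],
                           "repetition": [1], "hbt_um": [50.0]})
        out = aggregate_repetitions(df)
        assert out["hbt_um"].tolist() == [50.0]

    def test_median_robust_to_one_outlier(self):
        df = pd.DataFrame({"subject_id": ["a"] * 3, "location": ["frontal_left"] * 3,
                           "repetition": [1, 2, 3], "hbt_um": [50.0, 50.0, 500.0]})
        assert aggregate_repetitions(df)["hbt_um"].iloc[0] == 50.0

    def test_failed_qc_repetitions_excluded(self):
        df = pd.DataFrame({
            "subject_id": ["a"] * 3 + ["b"],
            "location": ["frontal_left"] * 3 + ["frontal_left"],
            "repetition": [1, 2, 3, 1],
            "hbt_um": [50.0, 60.0, 999.0, 40.0],
            "qc_pass": [True, True, False, False],
        })
        out = aggregate_repetitions(df)
        assert out["hbt_um"].tolist() == [55.0]  # subject b fully dropped


class TestSexContrast:
    def test_injected_effect_direction_recovered(self):
        cfg = CohortConfig(seed=1, sex_effects=SexEffects(hbt=1.0, so2=1.0, cbfi=0.7))
        agg, subjects = truth_cohort(cfg)
        res = lme_sex_contrast(agg, subjects, "cbfi_cm2s")
        assert res.estimate < 0  # males lower when M/F ratio < 1
        assert res.p_value < 0.05

    def test_noise_free_contrast_matches_injected_magnitude(self):
        cfg = CohortConfig(seed=2, variability=zero_variability(),
                           noise=zero_noise(),
                           sex_effects=SexEffects(hbt=1.2, so2=1.0, cbfi=1.0),
                           ga_slopes=GASlopes(hbt_um_per_week=0.0, so2_per_week=0.0))
        agg, subjects = truth_cohort(cfg)
        res = lme_sex_contrast(agg, subjects, "hbt_um")
        base = cfg.baseline.hbt_um
        expected = base * (1.2**0.5 - 1.2**-0.5)
        assert res.estimate == pytest.approx(expected, rel=1e-6)

    def test_constant_response_gives_zero_contrast(self):
        cfg = CohortConfig(seed=3, variability=zero_variability(),
                           noise=zero_noise()).null_effects()
        agg, subjects = truth_cohort(cfg)
        res = lme_sex_contrast(agg, subjects, "hbt_um")
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_requires_two_subjects_per_sex(self):
        cfg = CohortConfig(n_male=1, n_female=4, seed=4)
        agg, subjects = truth_cohort(cfg)
        with pytest.raises(DegenerateDesignError):
            lme_sex_contrast(agg, subjects, "hbt_um")

    def test_null_type_i_error_is_nominal(self):
        """Rejection rate under the null stays inside the binomial band."""
        n_reps, alpha = 120, 0.05
        null_cfg = CohortConfig().null_effects()
        rej = 0
        for s in range(n_reps):
            agg, subjects = truth_cohort(null_cfg.model_copy(update={"seed": 20_000 + s}))
            rej += lme_sex_contrast(agg, subjects, "cbfi_cm2s").p_value < alpha
        half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rej / n_reps - alpha) <= half


class TestGATrend:
    def test_noise_free_slope_recovered(self):
        cfg = CohortConfig(seed=5, variability=zero_variability(), noise=zero_noise(),
                           sex_effects=SexEffects(hbt=1.0, so2=1.0, cbfi=1.0))
        agg, subjects = truth_cohort(cfg)
        res = lme_ga_trend(agg, subjects, "hbt_um")
        assert res.estimate == pytest.approx(cfg.ga_slopes.hbt_um_per_week, rel=0.01)
        assert res.p_value < 1e-6

    def test_constant_ga_is_degenerate(self):
        cfg = CohortConfig(seed=6, ga_sd_weeks=0.0, ga_range_weeks=(39.2, 39.2))
        agg, subjects = truth_cohort(cfg)
        with pytest.raises(DegenerateDesignError):
            lme_ga_trend(agg, subjects, "hbt_um")

    def test_null_slope_rejection_rate_nominal(self):
        n_reps, alpha = 60, 0.05
        null_cfg = CohortConfig().null_effects()
        rej = 0
        for s in range(n_reps):
            agg, subjects = truth_cohort(null_cfg.model_copy(update={"seed": 40_000 + s}))
            rej += lme_ga_trend(agg, subjects, "hbt_um").p_value < alpha
        half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rej / n_reps - alpha) <= half + 0.01


class TestPearson:
    def test_perfectly_linear_and_antilinear(self):
        subjects = pd.DataFrame({"subject_id": list("abcde"),
                                 "ga_weeks": [37.0, 38, 39, 40, 41]})
        rec = pd.DataFrame({"subject_id": list("abcde"),
                            "hbt_um": [40.0, 45, 50, 55, 60],
                            "location": ["frontal_left"] * 5})
        r, p = pearson_ga(rec, subjects, "hbt_um")
        assert r == pytest.approx(1.0)
        rec["hbt_um"] = rec["hbt_um"].iloc[::-1].to_numpy()
        r, _ = pearson_ga(rec, subjects, "hbt_um")
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        subjects = pd.DataFrame({"subject_id": list("abc"), "ga_weeks": [38.0, 39, 40]})
        rec = pd.DataFrame({"subject_id": list("abc"), "hbt_um": [50.0] * 3,
                            "location": ["frontal_left"] * 3})
        with pytest.raises(DegenerateDesignError):
            pearson_ga(rec, subjects, "hbt_um")

    def test_default_cohort_reproduces_target_correlation(self):
        """GA slope defaults target R ≈ 0.49 at the default cohort size."""
        rs = []
        for s in range(12):
            agg, subjects = truth_cohort(CohortConfig(seed=60_000 + s))
            rs.append(pearson_ga(agg, subjects, "hbt_um")[0])
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - 0.49) < max(3 * se, 0.12)


class TestDemographicsTTest:
    def test_identical_groups(self):
        subjects = pd.DataFrame({"subject_id": list("abcd"),
                                 "sex": ["M", "M", "F", "F"],
                                 "ga_weeks": [39.0, 39.0, 39.0, 39.0]})
        res = demographics_ttest(subjects, "ga_weeks")
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(1)
        subjects = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(200)],
            "sex": ["M"] * 100 + ["F"] * 100,
            "ga_weeks": np.concatenate([rng.normal(40, 0.5, 100),
                                        rng.normal(38, 0.5, 100)]),
        })
        assert demographics_ttest(subjects, "ga_weeks").p_value < 1e-10

    def test_matches_permutation_test(self):
        """Student's t p-value vs an exact-ish permutation p on small samples."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            m = rng.normal(0.3, 1.0, 8)
            f = rng.normal(0.0, 1.0, 6)
            subjects = pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(14)],
                "sex": ["M"] * 8 + ["F"] * 6,
                "x": np.concatenate([m, f]),
            })
            res = demographics_ttest(subjects, "x")
            perm = sps.permutation_test(
                (m, f), lambda a, b: np.mean(a) - np.mean(b),
                n_resamples=20_000, alternative="two-sided",
                random_state=np.random.default_rng(trial))
            assert abs(res.p_value - perm.pvalue) < 0.02


def test_percent_side_difference_requires_lateral_records():
    df = pd.DataFrame({"subject_id": ["a"], "location": ["frontal_mid"],
                       "cbfi_cm2s": [2e-8]})
    with pytest.raises(DegenerateDesignError):
        percent_side_difference(df, "cbfi_cm2s")
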