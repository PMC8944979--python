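"""Mixed models, ICC(A,1), power and group summaries against oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from condylometry.phantoms import CohortSpec, simulate_cohort
from condylometry.stats import (ICCResult, PowerSpec, analyze_study,
                                fit_random_intercept, group_summaries, icc_a1,
                                round_power, two_sample_power, validate_cohort)

# fixed 6x3 rater table used for the mean-squares oracle
ICC_TABLE = np.array(
    [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]], dtype=float
)


def icc_a1_oracle(x):
    """Straight transcription of the two-way mean-squares formula."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = (((x - grand) ** 2).sum()
           - k * ((x.mean(1) - grand) ** 2).sum()
           - n * ((x.mean(0) - grand) ** 2).sum()) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestRandomIntercept:
    def test_independent_rows_reduce_to_ols(self):
        """With no subject-level variance the REML fit equals OLS."""
        data = simulate_cohort(CohortSpec(slopes={"gonial_deg": -15.0},
                                          tau=0.0, sigma=120.0, seed=5))
        fit = fit_random_intercept(data, covariates=["gonial_deg"])
        ols = sm.OLS(data["volume_mm3"].to_numpy(),
                     sm.add_constant(data["gonial_deg"].to_numpy())).fit()
        assert fit.effects["gonial_deg"].slope == pytest.approx(ols.params[1], rel=1e-6)

    def test_duplicated_rows_leave_slope_at_ols_value(self):
        """Two identical rows per subject: the GLS slope equals the
        one-row-per-subject OLS slope, and the duplication loads onto the
        between-subject variance component."""
        rng = np.random.default_rng(4)
        n = 30
        x = rng.normal(120, 6, n)
        y = 700 - 12 * (x - 120) + rng.normal(0, 200, n)
        base = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                             "volume_mm3": y, "gonial_deg": x,
                             "sex": "F", "age_years": 30.0})
        dup = pd.concat([base.assign(side="R"), base.assign(side="L")],
                        ignore_index=True)
        fit = fit_random_intercept(dup, covariates=["gonial_deg"])
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.effects["gonial_deg"].slope == pytest.approx(ols.params[1], rel=1e-4)
        assert fit.tau2 > 100 * fit.sigma2

    def test_slope_equivariant_under_covariate_scaling(self):
        data = simulate_cohort(CohortSpec(seed=7))
        fit1 = fit_random_intercept(data, covariates=["gonial_deg"])
        scaled = data.assign(gonial_deg=data["gonial_deg"] * 10.0)
        fit10 = fit_random_intercept(scaled, covariates=["gonial_deg"])
        assert fit10.effects["gonial_deg"].slope == pytest.approx(
            fit1.effects["gonial_deg"].slope / 10.0, rel=1e-6)

    def test_wald_interval_contains_slope(self):
        data = simulate_cohort(CohortSpec(seed=2))
        fit = fit_random_intercept(data, covariates=["divergence_deg", "sex"])
        e = fit.effects["divergence_deg"]
        assert e.ci_low <= e.slope <= e.ci_high
        assert fit.tau2 >= 0 and fit.sigma2 >= 0
        assert fit.n_subjects == 73 and fit.n_condyles == 146

    def test_too_few_subjects_rejected(self):
        data = simulate_cohort(CohortSpec(seed=1)).iloc[:4]
        with pytest.raises(ValueError, match="3 subjects"):
            fit_random_intercept(data, covariates=["gonial_deg"])

    def test_collinear_design_names_columns(self):
        data = simulate_cohort(CohortSpec(seed=1)).assign(
            gonial_twice=lambda d: 2 * d["gonial_deg"])
        with pytest.raises(ValueError, match="collinear.*gonial"):
            fit_random_intercept(data, covariates=["gonial_deg", "gonial_twice"])


class TestAnalyzeStudy:
    def test_report_shape(self):
        report = analyze_study(simulate_cohort(CohortSpec(seed=3)))
        for cov in ("anb_deg", "divergence_deg", "gonial_deg"):
            block = report["continuous"][cov]
            assert set(block) == {"crude", "adjusted", "stratified"}
            assert set(block["stratified"]) == {"F", "M"}
        for axis in ("skeletal_class", "divergence_class", "growth_class"):
            assert "reference" in report["categorical"][axis]

    def test_stratified_fits_recover_sex_specific_slopes(self):
        """Cohorts with female gonial slope -10 and male slope -1: the
        per-sex age-adjusted fits recover both within Monte-Carlo error."""
        f_slopes, m_slopes = [], []
        for seed in range(1, 41):
            data = simulate_cohort(CohortSpec(
                slopes={"gonial_deg": (-10.0, -1.0)}, seed=seed))
            rep = analyze_study(data)
            strat = rep["continuous"]["gonial_deg"]["stratified"]
            f_slopes.append(strat["F"].effects["gonial_deg"].slope)
            m_slopes.append(strat["M"].effects["gonial_deg"].slope)
        assert np.mean(f_slopes) == pytest.approx(-10.0, abs=3.0)
        assert np.mean(m_slopes) == pytest.approx(-1.0, abs=3.0)

    def test_small_stratum_reported_unavailable_not_fatal(self):
        data = simulate_cohort(CohortSpec(n_female=10, n_male=2, seed=1))
        report = analyze_study(data)
        strat = report["continuous"]["gonial_deg"]["stratified"]
        assert "unavailable" in strat["M"]
        assert strat["F"].n_subjects == 10

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            analyze_study(simulate_cohort(CohortSpec(seed=1)).iloc[:0])


class TestICC:
    def test_fixed_table_matches_mean_squares_oracle(self):
        res = icc_a1(ICC_TABLE)
        assert res.icc == pytest.approx(icc_a1_oracle(ICC_TABLE), abs=1e-12)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_fixed_table_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = ICC_TABLE.shape
        df = pd.DataFrame({"subj": np.repeat(np.arange(n), k),
                           "rater": np.tile(np.arange(k), n),
                           "y": ICC_TABLE.ravel()})
        ref = pg.intraclass_corr(df, "subj", "rater", "y")
        row = ref.loc[ref["Type"] == "ICC(A,1)"].iloc[0]
        res = icc_a1(ICC_TABLE)
        assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_identical_raters_give_exactly_one(self):
        x = np.tile(np.array([[300.0], [700.0], [1100.0], [1400.0]]), (1, 3))
        res = icc_a1(x)
        assert res.icc == 1.0

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(11)
        res = icc_a1(rng.normal(0, 1, size=(50, 3)))
        assert abs(res.icc) < 0.15

    def test_invariant_under_shift_and_subject_relabeling(self):
        res0 = icc_a1(ICC_TABLE)
        assert icc_a1(ICC_TABLE + 57.3).icc == pytest.approx(res0.icc, abs=1e-12)
        perm = np.random.default_rng(0).permutation(ICC_TABLE.shape[0])
        assert icc_a1(ICC_TABLE[perm]).icc == pytest.approx(res0.icc, abs=1e-12)

    def test_missing_cells_rejected(self):
        x = ICC_TABLE.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_a1(x)


class TestPower:
    def test_null_power_equals_alpha(self):
        spec = PowerSpec(700.0, 700.0, 250.0, 20, 40, alpha=0.05)
        assert two_sample_power(spec) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_effect_size(self):
        powers = [two_sample_power(PowerSpec(650 + d, 650, 250, 20, 40))
                  for d in (50, 150, 400, 1200)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_symmetric_in_groups(self):
        assert two_sample_power(PowerSpec(850, 650, 250, 20, 40)) == pytest.approx(
            two_sample_power(PowerSpec(650, 850, 250, 40, 20)), abs=1e-12)

    def test_increasing_in_each_group_size(self):
        base = two_sample_power(PowerSpec(850, 650, 250, 20, 40))
        assert two_sample_power(PowerSpec(850, 650, 250, 30, 40)) > base
        assert two_sample_power(PowerSpec(850, 650, 250, 20, 60)) > base

    @pytest.mark.parametrize("kw", [dict(sd=0.0), dict(n1=1), dict(alpha=1.5)])
    def test_invalid_spec_rejected(self, kw):
        args = dict(mean1=850.0, mean2=650.0, sd=250.0, n1=20, n2=40, alpha=0.05)
        args.update(kw)
        with pytest.raises(ValueError):
            PowerSpec(**args)

    def test_round_power_is_half_up(self):
        assert round_power(0.815) == 0.82
        assert round_power(0.8149) == 0.81


class TestGroupSummaries:
    def test_two_point_level(self):
        df = pd.DataFrame({"divergence_class": ["hypo", "hypo"],
                           "volume_mm3": [600.0, 800.0]})
        out = group_summaries(df, "divergence_class")
        row = out.loc["hypo"]
        assert row["mean"] == 700.0 and row["median"] == 700.0
        assert row["sd"] == pytest.approx(141.4213562, abs=1e-6)
        assert row["min"] == 600.0 and row["max"] == 800.0

    def test_empty_levels_reported_with_zero_count(self):
        df = pd.DataFrame({"growth_class": ["normal"] * 3,
                           "volume_mm3": [500.0, 700.0, 900.0]})
        out = group_summaries(df, "growth_class")
        assert out.loc["normal", "n_condyles"] == 3
        assert out.loc["horizontal", "n_condyles"] == 0
        assert out.loc["post_rotation", "n_condyles"] == 0


class TestValidateCohort:
    def test_valid_table_passes(self):
        validate_cohort(simulate_cohort(CohortSpec(seed=1)))

    def test_three_condyles_per_subject_rejected(self):
        data = simulate_cohort(CohortSpec(seed=1))
        extra = data.iloc[[0]].assign(side="R")
        bad = pd.concat([data, extra], ignore_index=True)
        with pytest.raises(ValueError):
            validate_cohort(bad)

    def test_nonpositive_volume_rejected(self):
        data = simulate_cohort(CohortSpec(seed=1)).copy()
        data.loc[0, "volume_mm3"] = -5.0
        with pytest.raises(ValueError, match="positive"):
            validate_cohort(data)
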