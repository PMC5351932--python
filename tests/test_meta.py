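"""Meta-analysis pooling, summary-statistic tests, cross-region mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainmeth.meta import (
    CohortEstimate,
    GroupSummary,
    adjusted_group_summaries,
    fit_cross_region,
    meta_fixed,
    meta_from_groups,
    welch_from_summary,
)
from brainmeth.studydata import cohort_age_summaries


class TestWelchFromSummary:
    def test_published_age_row_reproduced(self):
        """The two-brain-bank study's PFC age row gives p rounding to 1.00."""
        res = welch_from_summary(62.05, 15.87, 20, 62.04, 18.74, 23)
        assert round(res["p"], 2) == 1.00

    def test_identical_summaries(self):
        res = welch_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_textbook_example(self):
        res = welch_from_summary(1.0, 1.0, 10, 2.0, 1.0, 10)
        assert res["t"] == pytest.approx(-2.23607, abs=1e-4)
        assert res["df"] == pytest.approx(18.0, abs=1e-9)
        assert res["p"] == pytest.approx(0.0382, abs=1e-3)

    def test_degenerate_zero_variance(self):
        same = welch_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5)
        assert same["p"] == 1.0 and same["status"] == "degenerate"
        diff = welch_from_summary(3.0, 0.0, 5, 4.0, 0.0, 5)
        assert diff["p"] == 0.0 and diff["status"] == "degenerate"

    def test_all_published_age_rows_reproduce_to_two_decimals(self):
        printed = {
            ("LNDBB", "PFC"): 1.00, ("LNDBB", "STR"): 0.74, ("LNDBB", "HC"): 0.85,
            ("LNDBB", "CER"): 0.95, ("DBCBB", "PFC"): 0.56, ("DBCBB", "STR"): 0.92,
            ("DBCBB", "CER"): 0.85,
        }
        table = cohort_age_summaries()
        for (cohort, region), expected in printed.items():
            sub = table[(table.cohort == cohort) & (table.region == region)]
            case = sub[sub.group == "case"].iloc[0]
            ctl = sub[sub.group == "control"].iloc[0]
            res = welch_from_summary(
                case.age_mean, case.age_sd, case.n, ctl.age_mean, ctl.age_sd, ctl.n
            )
            assert round(res["p"], 2) == pytest.approx(expected)


class TestMetaFixed:
    def test_single_cohort_passthrough(self):
        res = meta_fixed([CohortEstimate("a", 0.3, 0.1)])
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)

    def test_equal_se_average(self):
        res = meta_fixed(
            [CohortEstimate("a", 0.5, 0.1), CohortEstimate("b", 0.2, 0.1)]
        )
        assert res.estimate == pytest.approx(0.35)
        assert res.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-6)

    def test_inverse_variance_weight_arithmetic(self):
        res = meta_fixed(
            [CohortEstimate("a", 0.5, 0.1), CohortEstimate("b", 0.2, 0.2)]
        )
        assert res.estimate == pytest.approx(0.44)
        assert res.se == pytest.approx(0.0894, abs=1e-4)
        assert res.z == pytest.approx(4.92, abs=1e-2)

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(1, 6)
            est = rng.normal(0, 1, k)
            se = rng.uniform(0.05, 0.5, k)
            res = meta_fixed(
                [CohortEstimate(str(i), est[i], se[i]) for i in range(k)]
            )
            w = 1 / se**2
            assert res.estimate == pytest.approx(np.sum(w * est) / np.sum(w), abs=1e-12)
            assert res.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)

    def test_combined_se_decreases_with_cohorts(self):
        comps = [CohortEstimate(str(i), 0.1, 0.2) for i in range(5)]
        ses = [meta_fixed(comps[: k + 1]).se for k in range(5)]
        assert all(a > b for a, b in zip(ses, ses[1:]))
        assert meta_fixed(comps).se <= min(c.se for c in comps)

    def test_order_and_scale_invariance(self):
        comps = [
            CohortEstimate("a", 0.5, 0.1),
            CohortEstimate("b", -0.2, 0.3),
            CohortEstimate("c", 0.1, 0.15),
        ]
        fwd = meta_fixed(comps)
        rev = meta_fixed(comps[::-1])
        assert fwd.estimate == pytest.approx(rev.estimate, abs=1e-14)
        scaled = meta_fixed(
            [CohortEstimate(c.cohort, 3 * c.estimate, 3 * c.se) for c in comps]
        )
        assert scaled.estimate == pytest.approx(3 * fwd.estimate, abs=1e-12)
        assert scaled.z == pytest.approx(fwd.z, abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([CohortEstimate("a", 0.1, 0.0)])


class TestMetaFromGroups:
    def test_single_cohort_equals_mean_difference(self):
        g = GroupSummary("a", 0.55, 0.05, 20, 0.50, 0.04, 25)
        res = meta_from_groups([g])
        assert res.estimate == pytest.approx(0.05)
        assert res.se == pytest.approx(np.sqrt(0.05**2 / 20 + 0.04**2 / 25))

    def test_two_identical_cohorts_halve_variance(self):
        g = GroupSummary("a", 0.55, 0.05, 20, 0.50, 0.04, 25)
        one = meta_from_groups([g])
        two = meta_from_groups([g, GroupSummary("b", *list(g.__dict__.values())[1:])])
        assert two.estimate == pytest.approx(one.estimate)
        assert two.se == pytest.approx(one.se / np.sqrt(2), abs=1e-12)

    def test_agrees_with_meta_fixed_on_same_pairs(self):
        rng = np.random.default_rng(4)
        groups, comps = [], []
        for i in range(3):
            m1, s1, n1 = rng.normal(0.5, 0.1), rng.uniform(0.02, 0.1), 30
            m0, s0, n0 = rng.normal(0.5, 0.1), rng.uniform(0.02, 0.1), 35
            groups.append(GroupSummary(str(i), m1, s1, n1, m0, s0, n0))
            comps.append(
                CohortEstimate(str(i), m1 - m0, np.sqrt(s1**2 / n1 + s0**2 / n0))
            )
        a, b = meta_from_groups(groups), meta_fixed(comps)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_covariate_adjustment_preserves_group_contrast(self):
        """Residualizing on covariates only leaves the diagnosis effect."""
        rng = np.random.default_rng(5)
        n = 60
        is_case = np.arange(n) < 30
        age = rng.normal(60, 10, n)
        y = 0.5 + 0.03 * is_case + 0.002 * (age - 60) + 0.01 * rng.standard_normal(n)
        g = adjusted_group_summaries(y, age[:, None], is_case, "a")
        assert g.mean1 - g.mean0 == pytest.approx(0.03, abs=0.01)


def _balanced_long(seed, effect=0.03, donor_sd=0.0, resid=0.02, n_donors=40):
    rng = np.random.default_rng(seed)
    diag = np.array(["case"] * (n_donors // 2) + ["control"] * (n_donors // 2))
    age = rng.normal(60, 10, n_donors)
    sex = rng.choice(["M", "F"], n_donors)
    u = donor_sd * rng.standard_normal(n_donors)
    rows = []
    for d in range(n_donors):
        for reg in ("PFC", "STR", "HC"):
            rows.append(
                {
                    "beta": 0.5 + effect * (diag[d] == "case") + 0.001 * (age[d] - 60)
                    + u[d] + resid * rng.standard_normal(),
                    "diagnosis": diag[d], "sex": sex[d], "age": age[d],
                    "donor": f"D{d}", "region": reg,
                }
            )
    return pd.DataFrame(rows)


class TestCrossRegionMixedModel:
    def test_degenerate_limit_matches_pooled_ols(self):
        import statsmodels.formula.api as smf

        long = _balanced_long(5, donor_sd=0.0)
        fit = fit_cross_region(long, covariates=("sex", "age"), exclude_regions=())
        long["_exposure"] = (long["diagnosis"] == "case").astype(float)
        ols = smf.ols("beta ~ _exposure + C(sex) + age", long).fit()
        assert fit.estimate / 100 == pytest.approx(ols.params["_exposure"], abs=1e-6)

    def test_donor_correlation_inflates_se_over_naive_ols(self):
        import statsmodels.formula.api as smf

        long = _balanced_long(6, donor_sd=0.03)
        fit = fit_cross_region(long, covariates=("sex", "age"), exclude_regions=())
        long["_exposure"] = (long["diagnosis"] == "case").astype(float)
        ols = smf.ols("beta ~ _exposure + C(sex) + age", long).fit()
        assert fit.se / 100 > ols.bse["_exposure"]
        assert fit.var_donor > 0

    def test_recovers_homogeneous_effect(self):
        """Mean estimate over 20 seeds within +-0.01 of the 0.03 truth."""
        ests = [
            fit_cross_region(
                _balanced_long(s, donor_sd=0.02), covariates=("sex", "age"),
                exclude_regions=(),
            ).estimate / 100
            for s in range(20)
        ]
        assert abs(np.mean(ests) - 0.03) <= 0.01

    def test_permuted_exposure_null_p_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for s in range(10):
            long = _balanced_long(s + 50, effect=0.0, donor_sd=0.02)
            ps.append(
                fit_cross_region(
                    long, covariates=("sex", "age"), exclude_regions=()
                ).p
            )
        # no gross anticonservatism: not all small, not all large
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cerebellum_excluded_by_default(self):
        long = _balanced_long(7, donor_sd=0.02)
        long.loc[long["region"] == "HC", "region"] = "CER"
        default = fit_cross_region(long, covariates=("sex", "age"))
        explicit = fit_cross_region(
            long[long["region"] != "CER"], covariates=("sex", "age"),
            exclude_regions=(),
        )
        assert default.estimate == pytest.approx(explicit.estimate, abs=1e-9)

    def test_single_region_rejected(self):
        long = _balanced_long(8)
        long["region"] = "PFC"
        with pytest.raises(ValueError):
            fit_cross_region(long, exclude_regions=())
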