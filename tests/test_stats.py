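"""Statistical battery: closed forms, cross-checks, calibration identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hemiasym import (
    ancova_on_as,
    bonferroni,
    build_design,
    glm_group_by_hemisphere,
    one_sample_t,
    paired_t,
    partial_correlation,
    run_statistics,
    two_sample_t,
)
from hemiasym.stats import chi_square_counts


def make_cohort(n_bd=20, n_nc=25, seed=0):
    rng = np.random.default_rng(seed)
    n = n_bd + n_nc
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": ["BD"] * n_bd + ["NC"] * n_nc,
            "age": rng.integers(21, 51, size=n),
            "gender": rng.choice(["M", "F"], size=n),
        }
    )


class TestTTests:
    def test_one_sample_closed_form(self):
        # mean 2, sd 1, n 3: t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = one_sample_t([1.0, 2.0, 3.0])
        assert res.value == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.df == 2

    def test_one_sample_symmetric_data_is_zero(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0], mu0=0.0)
        assert res.value == 0.0

    def test_one_sample_single_observation_errors(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])

    def test_one_sample_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 1.0, size=25)
        res = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_two_sample_hand_derived(self):
        # pooled SD = 1 -> t = (2 - 3) / sqrt(1 * (1/3 + 1/3)) = -1.2247
        res = two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.value == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4

    def test_two_sample_identical_samples_zero(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == 0.0

    def test_two_sample_pooled_df_convention(self):
        # 49 + 61 subjects give the df = 108 of a Student (not Welch) test
        rng = np.random.default_rng(2)
        res = two_sample_t(rng.normal(size=49), rng.normal(size=61))
        assert res.df == 108

    def test_two_sample_matches_scipy_student(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=15), rng.normal(0.4, 1.2, size=20)
        res = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_paired_is_one_sample_on_differences(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)

    def test_paired_constant_difference_errors(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            paired_t(x + 2.0, x)


class TestGLM:
    def test_equal_hemispheres_give_null_within_effects(self):
        cohort = make_cohort(seed=5)
        design = build_design(cohort)
        rng = np.random.default_rng(5)
        vals = rng.normal(0.3, 0.05, size=len(cohort))
        glm = glm_group_by_hemisphere(vals, vals.copy(), design)
        assert glm["hemisphere"].value == pytest.approx(0.0, abs=1e-20)
        assert glm["group_x_hemisphere"].value == pytest.approx(0.0, abs=1e-20)
        assert glm["hemisphere"].p > 0.99

    def test_f_equals_t_squared_against_difference_regression(self):
        cohort = make_cohort(seed=6)
        design = build_design(cohort)
        rng = np.random.default_rng(6)
        left = rng.normal(0.3, 0.05, size=len(cohort))
        right = left + rng.normal(0.01, 0.02, size=len(cohort))
        glm = glm_group_by_hemisphere(left, right, design)
        # independent route: OLS of R-L on the same design via lstsq + t
        X = np.hstack([np.ones((len(cohort), 1)), design.to_numpy()])
        y = right - left
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = len(y) - X.shape[1]
        cov = np.linalg.inv(X.T @ X) * (resid @ resid / df)
        t_int = beta[0] / np.sqrt(cov[0, 0])
        t_grp = beta[1] / np.sqrt(cov[1, 1])
        assert glm["hemisphere"].value == pytest.approx(t_int**2, rel=1e-9)
        assert glm["group_x_hemisphere"].value == pytest.approx(t_grp**2, rel=1e-9)
        assert glm["group_x_hemisphere"].df == (1.0, float(df))

    def test_matches_pingouin_mixed_anova_without_covariates(self):
        # balanced groups: the effect-coded marginal-mean convention and
        # pingouin's classical sums of squares coincide
        pg = pytest.importorskip("pingouin")
        cohort = make_cohort(n_bd=16, n_nc=16, seed=7)
        rng = np.random.default_rng(7)
        left = rng.normal(0.3, 0.05, size=len(cohort))
        right = left + rng.normal(0.02, 0.03, size=len(cohort))
        design = build_design(cohort)[["group_ec"]]
        glm = glm_group_by_hemisphere(left, right, design)
        long = pd.DataFrame(
            {
                "subject": np.repeat(cohort["subject_id"].to_numpy(), 2),
                "hemi": ["L", "R"] * len(cohort),
                "group": np.repeat(cohort["group"].to_numpy(), 2),
                "y": np.column_stack([left, right]).ravel(),
            }
        )
        aov = pg.mixed_anova(data=long, dv="y", within="hemi",
                             between="group", subject="subject")
        ref = {row["Source"]: row["F"] for _, row in aov.iterrows()}
        assert glm["group"].value == pytest.approx(ref["group"], rel=1e-6)
        assert glm["hemisphere"].value == pytest.approx(ref["hemi"], rel=1e-6)
        assert glm["group_x_hemisphere"].value == pytest.approx(
            ref["Interaction"], rel=1e-6
        )

    def test_rank_deficient_design_names_columns(self):
        cohort = make_cohort(seed=8)
        design = build_design(cohort)
        design["dup"] = design["age_c"]
        rng = np.random.default_rng(8)
        v = rng.normal(size=len(cohort))
        with pytest.raises(ValueError, match="collinear"):
            glm_group_by_hemisphere(v, v + 0.1, design)


class TestAncova:
    def test_identical_groups_give_near_zero_f(self):
        cohort = make_cohort(n_bd=20, n_nc=20, seed=9)
        # AS depends only on covariates, identically across groups
        design = build_design(cohort)
        as_vals = 0.5 * design["age_c"].to_numpy()
        res = ancova_on_as(as_vals + 1e-9 * np.random.default_rng(9).normal(
            size=len(cohort)), cohort, design)
        assert res.value < 1.0

    def test_covariate_free_ancova_equals_t_squared(self):
        cohort = make_cohort(seed=10)
        rng = np.random.default_rng(10)
        as_vals = rng.normal(0.0, 1.0, size=len(cohort))
        as_vals[cohort["group"] == "BD"] += 0.8
        design = build_design(cohort)[["group_ec"]]
        res = ancova_on_as(as_vals, cohort, design)
        is_bd = (cohort["group"] == "BD").to_numpy()
        t = two_sample_t(as_vals[is_bd], as_vals[~is_bd])
        assert res.value == pytest.approx(t.value**2, rel=1e-9)
        assert res.p == pytest.approx(t.p, rel=1e-9)

    def test_permutation_calibration(self):
        # permuting group labels should reject at about the nominal rate
        cohort = make_cohort(n_bd=25, n_nc=25, seed=11)
        rng = np.random.default_rng(11)
        as_vals = rng.normal(size=len(cohort))
        design = build_design(cohort)
        reps, rej = 400, 0
        groups = cohort["group"].to_numpy().copy()
        for _ in range(reps):
            perm = cohort.copy()
            perm["group"] = rng.permutation(groups)
            res = ancova_on_as(as_vals, perm, build_design(perm))
            rej += res.p < 0.05
        rate = rej / reps
        ci = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < ci + 0.01


class TestBonferroni:
    def test_threshold_arithmetic(self):
        mask, adj, thr = bonferroni([0.01, 0.0005], alpha=0.05, m=45)
        assert thr == pytest.approx(0.05 / 45)
        assert not mask[0] and mask[1]
        assert adj[0] == pytest.approx(0.45)

    def test_family_of_one_is_uncorrected(self):
        mask, adj, thr = bonferroni([0.04], alpha=0.05, m=1)
        assert mask[0] and thr == 0.05 and adj[0] == 0.04

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=50)
        m1, _, _ = bonferroni(p, alpha=0.01)
        m2, _, _ = bonferroni(p, alpha=0.05)
        assert (m1 <= m2).all()


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = partial_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.value == pytest.approx(ref_r, abs=1e-12)
        assert res.p == pytest.approx(ref_p, abs=1e-9)

    def test_spearman_no_covariates_matches_scipy(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=35)
        y = x**3 + rng.normal(scale=0.5, size=35)
        res = partial_correlation(x, y, method="spearman")
        ref = sps.spearmanr(x, y)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)

    def test_covariate_explained_y_has_near_zero_partial_r(self):
        rng = np.random.default_rng(15)
        c = rng.normal(size=60)
        x = rng.normal(size=60)
        y = 2.0 + 3.0 * c + 1e-8 * rng.normal(size=60)
        res = partial_correlation(x, y, covariates=c)
        assert abs(res.value) < 0.3

    def test_exactly_constant_residual_errors(self):
        c = np.linspace(0, 1, 30)
        y = 2.0 + 3.0 * c
        x = np.random.default_rng(16).normal(size=30)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, y, covariates=c)

    def test_known_partial_structure(self):
        # x and y share only the covariate; partialling it removes the link
        rng = np.random.default_rng(17)
        c = rng.normal(size=500)
        x = c + rng.normal(scale=0.5, size=500)
        y = c + rng.normal(scale=0.5, size=500)
        raw = partial_correlation(x, y)
        part = partial_correlation(x, y, covariates=c)
        assert raw.value > 0.5
        assert abs(part.value) < 0.15


class TestChiSquare:
    def test_matches_scipy_pearson_uncorrected(self):
        table = [[28, 21], [32, 29]]
        res = chi_square_counts(table)
        chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
        assert res.value == pytest.approx(chi2, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 1.0


class TestRunStatistics:
    @pytest.fixture(scope="class")
    def small_run(self, fixture_cohort):
        from hemiasym import build_networks, cohort_asymmetry, compute_cohort_metrics
        cohort, conns, parc = fixture_cohort
        nets = build_networks(conns, parc)
        table = compute_cohort_metrics(nets, n_nulls=10, seed=1)
        asym = cohort_asymmetry(table)
        return asym, cohort

    def test_global_as_rows_cover_the_seven_properties(self, small_run):
        asym, cohort = small_run
        tables = run_statistics(asym, cohort)
        as_tests = tables["as_tests"]
        globals_present = set(
            as_tests.loc[~as_tests["metric"].str.startswith("Enodal:"), "metric"]
        )
        assert globals_present == {"Eg", "Eloc", "Cp", "Lp", "gamma", "lambda",
                                   "sigma"}

    def test_nodal_family_bonferroni_flagged(self, small_run):
        asym, cohort = small_run
        tables = run_statistics(asym, cohort)
        nodal = tables["glm_nodal"]
        assert (nodal["family_size"] == 10).all()
        assert nodal["corrected"].all()

    def test_correlations_patients_only_uncorrected(self, small_run):
        asym, cohort = small_run
        tables = run_statistics(asym, cohort)
        corr = tables["correlations"]
        n_bd = int((cohort["group"] == "BD").sum())
        assert (corr["n"] <= n_bd).all()
        assert (~corr["corrected"]).all()
        assert set(corr["clinical_score"]) <= {"YMRS", "HAMD"}

    def test_deterministic_given_inputs(self, small_run):
        asym, cohort = small_run
        t1 = run_statistics(asym, cohort)
        t2 = run_statistics(asym, cohort)
        for name in t1:
            pd.testing.assert_frame_equal(t1[name], t2[name])
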