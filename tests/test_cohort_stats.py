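"""t-tests, two-way ANOVAs and age regressions against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spacol import (
    CohortSpec,
    age_regression,
    generate_cohort,
    run_study_tables,
    twoway_anova,
    unpaired_ttest,
)
from spacol.cohort_stats import validate_cohort
from spacol.exceptions import (
    DegenerateFitError,
    DesignError,
    SampleSizeError,
    VocabularyError,
)


def pooled_ttest_oracle(a, b):
    """Hand-computed Student's pooled-variance t-test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def balanced_twoway_ss_oracle(table):
    """Brute-force sums-of-squares for a balanced a x b design with r reps.

    ``table[i, j]`` is the length-r replicate vector of cell (i, j). Returns
    (F_A, F_B, F_AB, df) computed from the textbook decomposition.
    """
    table = np.asarray(table, float)
    a, b, r = table.shape
    grand = table.mean()
    mean_a = table.mean(axis=(1, 2))
    mean_b = table.mean(axis=(0, 2))
    mean_ab = table.mean(axis=2)
    ss_a = b * r * np.sum((mean_a - grand) ** 2)
    ss_b = a * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_e = np.sum((table - mean_ab[:, :, None]) ** 2)
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1)
    return (
        (ss_a / df_a) / (ss_e / df_e),
        (ss_b / df_b) / (ss_e / df_e),
        (ss_ab / df_ab) / (ss_e / df_e),
        (df_a, df_b, df_ab, df_e),
    )


def table_to_frame(table):
    rows = []
    a, b, r = np.asarray(table).shape
    for i in range(a):
        for j in range(b):
            for k in range(r):
                rows.append({"fa": f"a{i}", "fb": f"b{j}", "y": table[i][j][k]})
    return pd.DataFrame(rows)


class TestUnpairedTTest:
    def test_identical_groups_are_null(self):
        r = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert r.df == 4

    def test_p_monotone_in_shift(self):
        base = [1.0, 2.0, 3.0]
        ps = [unpaired_ttest(base, [v + d for v in base]).p_value
              for d in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_pooled_variance_oracle(self):
        a = [310.0, 402.5, 365.0, 349.0]
        b = [255.0, 290.0, 301.5, 244.0]
        r = unpaired_ttest(a, b)
        t, p = pooled_ttest_oracle(a, b)
        assert r.t_statistic == pytest.approx(t, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)
        assert r.group_means == (pytest.approx(np.mean(a)), pytest.approx(np.mean(b)))

    def test_welch_mode_has_noninteger_df(self):
        r = unpaired_ttest([1.0, 2.0, 3.0], [10.0, 30.0, 50.0, 70.0],
                           equal_variance=False)
        assert r.df != int(r.df)

    def test_small_group_rejected(self):
        with pytest.raises(SampleSizeError):
            unpaired_ttest([1.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            unpaired_ttest([2.0, 2.0], [3.0, 3.0])


class TestTwowayAnova:
    def test_matches_brute_force_ss_oracle(self):
        rng = np.random.default_rng(21)
        table = rng.normal(50, 8, (2, 4, 3))
        table[1] += 6.0  # main effect of factor A
        res = twoway_anova(table_to_frame(table.tolist()), "y", "fa", "fb")
        f_a, f_b, f_ab, dfs = balanced_twoway_ss_oracle(table)
        got = dict(zip(res.factor_names, res.f_statistics))
        assert got["C(fa)"] == pytest.approx(f_a, rel=1e-10)
        assert got["C(fb)"] == pytest.approx(f_b, rel=1e-10)
        assert got["C(fa):C(fb)"] == pytest.approx(f_ab, rel=1e-10)
        assert res.residual_df == dfs[3]
        # p-values follow from the F distribution at the oracle df
        assert res.p_values[0] == pytest.approx(
            stats.f.sf(f_a, dfs[0], dfs[3]), rel=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(22)
        table = rng.normal(0, 1, (2, 2, 4))
        df = table_to_frame(table.tolist())
        shifted = df.assign(y=df["y"] + 1234.5)
        a = twoway_anova(df, "y", "fa", "fb")
        b = twoway_anova(shifted, "y", "fa", "fb")
        assert a.f_statistics == pytest.approx(b.f_statistics, rel=1e-9)

    def test_one_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(23)
        a = rng.normal(10, 2, 6)
        b = rng.normal(12, 2, 6)
        t = unpaired_ttest(a, b)
        # one-way F via the same pooled decomposition, computed by hand
        grand = np.concatenate([a, b]).mean()
        ss_between = 6 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_within = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        f = ss_between / (ss_within / 10)
        assert t.t_statistic ** 2 == pytest.approx(f, rel=1e-10)
        assert t.p_value == pytest.approx(stats.f.sf(f, 1, 10), rel=1e-10)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(24)
        df = table_to_frame(rng.normal(0, 1, (2, 3, 3)).tolist())
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = twoway_anova(df, "y", "fa", "fb")
        b = twoway_anova(shuffled, "y", "fa", "fb")
        assert a.f_statistics == pytest.approx(b.f_statistics, rel=1e-10)

    def test_balanced_design_ss_types_coincide(self):
        rng = np.random.default_rng(25)
        df = table_to_frame(rng.normal(0, 1, (2, 2, 5)).tolist())
        res = {t: twoway_anova(df, "y", "fa", "fb", ss_type=t) for t in (1, 2, 3)}
        for t in (2, 3):
            assert res[1].f_statistics == pytest.approx(
                res[t].f_statistics, rel=1e-9)

    def test_single_level_factor_rejected(self):
        df = table_to_frame(np.zeros((1, 2, 3)).tolist())
        df["y"] += np.arange(len(df))
        with pytest.raises(DesignError):
            twoway_anova(df, "y", "fa", "fb")

    def test_empty_cell_with_interaction_rejected(self):
        df = table_to_frame(np.random.default_rng(1).normal(0, 1, (2, 2, 3)).tolist())
        df = df[~((df["fa"] == "a1") & (df["fb"] == "b1"))]
        with pytest.raises(DesignError, match="empty"):
            twoway_anova(df, "y", "fa", "fb")

    def test_saturated_design_rejected(self):
        df = table_to_frame(np.random.default_rng(2).normal(0, 1, (2, 2, 1)).tolist())
        with pytest.raises(DesignError, match="residual|saturated"):
            twoway_anova(df, "y", "fa", "fb")


class TestAgeRegression:
    def _frame(self, ages, values):
        return pd.DataFrame({"age_months": ages, "mean_collagen_au": values})

    def test_collinear_points_have_unit_r_squared(self):
        df = self._frame([2.0, 5.0, 8.0, 11.0], [100.0, 160.0, 220.0, 280.0])
        r = age_regression(df)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(20.0)

    def test_confidence_interval_coverage(self):
        """95% CI for the slope covers the truth at near-nominal rate."""
        rng = np.random.default_rng(30)
        slope_true, cover, n = 40.0, 0, 10
        for _ in range(1000):
            x = rng.uniform(2, 12, n)
            y = 100.0 + slope_true * x + rng.normal(0, 60.0, n)
            r = age_regression(self._frame(x, y))
            half = stats.t.ppf(0.975, n - 2) * r.slope_stderr
            cover += (r.slope - half <= slope_true <= r.slope + half)
        assert 0.90 <= cover / 1000 <= 0.99

    def test_two_points_rejected(self):
        with pytest.raises(SampleSizeError):
            age_regression(self._frame([2.0, 5.0], [1.0, 2.0]))

    def test_constant_age_rejected(self):
        with pytest.raises(DegenerateFitError):
            age_regression(self._frame([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]))


class TestRunStudyTables:
    def test_group_swap_negates_t_and_keeps_p(self):
        df, _ = generate_cohort(CohortSpec(n_per_group=4, seed=3))
        tables = run_study_tables(df)
        swapped = df.copy()
        swapped["prolapse"] = ~swapped["prolapse"]
        swapped["genotype"] = swapped["genotype"].map(
            {"Fbln5_het": "Fbln5_ko", "Fbln5_ko": "Fbln5_het"})
        tables_sw = run_study_tables(swapped)
        for organ, r in tables.ttests.items():
            r2 = tables_sw.ttests[organ]
            assert r2.t_statistic == pytest.approx(-r.t_statistic, rel=1e-10)
            assert r2.p_value == pytest.approx(r.p_value, rel=1e-10)

    def test_empty_cohort_warns_instead_of_raising(self):
        empty = pd.DataFrame(columns=["animal_id", "genotype", "prolapse",
                                      "age_months", "organ", "mean_collagen_au"])
        tables = run_study_tables(empty)
        assert not tables.ttests
        assert tables.warnings

    def test_external_os_deficit_power(self):
        """An isolated external-os deficit is detected with high power while
        unaffected organs stay near the nominal false-positive rate."""
        spec_kwargs = dict(
            n_per_group=4,
            age_range_months=(4.0, 8.0),
            slopes_au_per_month={g: {o: 0.0 for o in
                                     ("uterus", "internal_os", "external_os", "vagina")}
                                 for g in ("normal", "prolapsed")},
            prolapsed_shift_au={"external_os": -250.0},
            between_animal_sigma=40.0,
            residual_sigma=55.0,
        )
        hits = {o: 0 for o in ("uterus", "internal_os", "external_os", "vagina")}
        n_rep = 200
        for rep in range(n_rep):
            df, _ = generate_cohort(CohortSpec(seed=1000 + rep, **spec_kwargs))
            tables = run_study_tables(df)
            for organ, r in tables.ttests.items():
                hits[organ] += r.p_value < 0.05
        assert hits["external_os"] / n_rep >= 0.90
        for organ in ("uterus", "internal_os", "vagina"):
            assert hits[organ] / n_rep <= 0.15

    def test_anova_terms_present(self):
        df, _ = generate_cohort(CohortSpec(n_per_group=6, seed=5))
        tables = run_study_tables(df)
        assert tables.anova_prolapse_organ is not None
        assert any("prolapse" in n for n in tables.anova_prolapse_organ.factor_names)
        assert tables.anova_age_prolapse is not None


class TestValidateCohort:
    def test_unknown_organ_rejected(self):
        df = pd.DataFrame([{"animal_id": "A", "genotype": "Fbln5_het",
                            "prolapse": False, "age_months": 5.0,
                            "organ": "spleen", "mean_collagen_au": 100.0}])
        with pytest.raises(VocabularyError):
            validate_cohort(df)

    def test_duplicate_record_rejected(self):
        row = {"animal_id": "A", "genotype": "Fbln5_het", "prolapse": False,
               "age_months": 5.0, "organ": "uterus", "mean_collagen_au": 100.0}
        with pytest.raises(DesignError):
            validate_cohort(pd.DataFrame([row, row]))
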