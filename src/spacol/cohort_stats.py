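"""Cohort-level statistics: t-tests, two-way ANOVAs and age regressions.

The study design this layer serves: two genotype groups (Fbln5 heterozygous
= normal, Fbln5 knockout = prolapsed), four organ cross-sections per animal,
ages 2-12 months, response = mean sPA collagen concentration (a.u.). The
age-matched comparison slice is ages 4-8 months inclusive. Analyses:

* unpaired two-sample t-tests (Student's pooled-variance by default, Welch
  optional) comparing normal vs prolapsed per organ on the age-matched slice;
* two-way factorial ANOVAs (Type II sums of squares by default; the balanced
  designs used here make Types I/II/III coincide) for prolapse x organ, and
  for age (binned or as a continuous covariate) with prolapse or organ;
* per-organ, per-group OLS regressions of collagen on age.

Raw per-test p-values are reported (no multiple-testing correction by
default; a Holm flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import (
    DegenerateFitError,
    DesignError,
    SampleSizeError,
    VocabularyError,
)
from .roi_quantify import ORGANS

COHORT_COLUMNS = (
    "animal_id", "genotype", "prolapse", "age_months", "organ", "mean_collagen_au"
)
GENOTYPES = ("Fbln5_het", "Fbln5_ko")
#: Age-matched slice (months, inclusive) for prolapse comparisons.
AGE_MATCHED_RANGE = (4.0, 8.0)


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (one row per animal x organ)."""
    df = pd.read_csv(path)
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise VocabularyError(f"cohort table missing columns {sorted(missing)}")
    bad_organs = set(df["organ"]) - set(ORGANS)
    if bad_organs:
        raise VocabularyError(f"unknown organ labels {sorted(bad_organs)}")
    bad_geno = set(df["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise VocabularyError(f"unknown genotype labels {sorted(bad_geno)}")
    if df.duplicated(["animal_id", "organ"]).any():
        raise DesignError("duplicate animal x organ records")
    df = df.copy()
    df["prolapse"] = df["prolapse"].astype(bool)
    df["age_months"] = df["age_months"].astype(float)
    df["mean_collagen_au"] = df["mean_collagen_au"].astype(float)
    return df


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test: statistic, df, two-sided p, group summaries."""

    t_statistic: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_ns: tuple[int, int]
    equal_variance: bool = True


def unpaired_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = True,
) -> TTestResult:
    """Unpaired two-sample t-test (Student's pooled-variance by default).

    Raises
    ------
    SampleSizeError
        If either group has fewer than 2 observations.
    DegenerateFitError
        If the pooled variance is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateFitError("zero variance in both groups; t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    df = a.size + b.size - 2 if equal_variance else float(res.df)
    return TTestResult(
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_ns=(int(a.size), int(b.size)),
        equal_variance=equal_variance,
    )


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA: per-term F statistics, p-values and df."""

    factor_names: tuple[str, ...]
    f_statistics: tuple[float, ...]
    p_values: tuple[float, ...]
    df_table: tuple[float, ...]
    residual_df: float
    ss_type: str = "II"

    def term(self, name: str) -> dict:
        i = self.factor_names.index(name)
        return {"F": self.f_statistics[i], "p": self.p_values[i],
                "df": self.df_table[i]}


def twoway_anova(
    records: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    ss_type: int = 2,
    interaction: bool = True,
) -> AnovaResult:
    """Two-way factorial ANOVA of ``response`` on two categorical factors.

    Fits ``response ~ C(a) * C(b)`` by OLS and decomposes with the requested
    sums-of-squares type (default Type II; for the balanced designs of this
    study all types coincide).

    Raises
    ------
    DesignError
        Fewer than 2 levels in a factor, an empty cell with interaction
        requested, or zero residual degrees of freedom.
    """
    df = records.dropna(subset=[response, factor_a, factor_b]).copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True).size()
    n_cells = df[factor_a].nunique() * df[factor_b].nunique()
    if interaction and len(cells) < n_cells:
        raise DesignError("empty design cell with interaction requested")
    op = "*" if interaction else "+"
    # type III is only meaningful under sum-to-zero contrasts
    coding = ", Sum" if ss_type == 3 else ""
    model = smf.ols(
        f"{response} ~ C({factor_a}{coding}) {op} C({factor_b}{coding})", data=df
    ).fit()
    if model.df_resid < 1:
        raise DesignError("saturated design: residual df = 0")
    table = sm.stats.anova_lm(model, typ=ss_type)
    terms = [t for t in table.index if t not in ("Residual", "Intercept")]
    return AnovaResult(
        factor_names=tuple(terms),
        f_statistics=tuple(float(table.loc[t, "F"]) for t in terms),
        p_values=tuple(float(table.loc[t, "PR(>F)"]) for t in terms),
        df_table=tuple(float(table.loc[t, "df"]) for t in terms),
        residual_df=float(table.loc["Residual", "df"]),
        ss_type={1: "I", 2: "II", 3: "III"}[ss_type],
    )


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS regression: slope, intercept, r^2, two-sided slope p, n."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float = float("nan")


def age_regression(records: pd.DataFrame, response: str = "mean_collagen_au") -> RegressionResult:
    """OLS of collagen (a.u.) on age (months) over the given cohort slice.

    Raises
    ------
    SampleSizeError
        Fewer than 3 records.
    DegenerateFitError
        Zero variance in age.
    """
    df = records.dropna(subset=[response, "age_months"])
    if len(df) < 3:
        raise SampleSizeError(f"regression needs >= 3 records; got {len(df)}")
    x = df["age_months"].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in age")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        n=len(df),
        slope_stderr=float(fit.stderr),
    )


@dataclass
class StudyTables:
    """Bundle of the per-organ and cohort-level analyses."""

    ttests: dict[str, TTestResult] = field(default_factory=dict)
    regressions: dict[tuple[str, str], RegressionResult] = field(default_factory=dict)
    anova_prolapse_organ: AnovaResult | None = None
    anova_age_prolapse: AnovaResult | None = None
    anova_age_organ: AnovaResult | None = None
    warnings: list[str] = field(default_factory=list)


def run_study_tables(
    cohort: pd.DataFrame,
    age_matched_range: tuple[float, float] = AGE_MATCHED_RANGE,
    age_bin_months: float = 4.0,
    equal_variance: bool = True,
) -> StudyTables:
    """Run the full per-organ analysis battery on a cohort table.

    For each organ: the normal-vs-prolapsed t-test on the age-matched slice
    and per-group age regressions (all ages). Cohort-wide: the prolapse x
    organ two-way ANOVA on the age-matched slice, and two-way ANOVAs of
    binned age (bins of ``age_bin_months``) with prolapse and with organ
    (without interaction, since the age bins are sparsely crossed).

    Missing slices are reported in ``warnings`` rather than raised.
    """
    cohort = validate_cohort(cohort)
    out = StudyTables()
    lo, hi = age_matched_range
    matched = cohort[(cohort["age_months"] >= lo) & (cohort["age_months"] <= hi)]
    for organ in ORGANS:
        sl = matched[matched["organ"] == organ]
        a = sl.loc[~sl["prolapse"], "mean_collagen_au"]
        b = sl.loc[sl["prolapse"], "mean_collagen_au"]
        try:
            out.ttests[organ] = unpaired_ttest(a, b, equal_variance=equal_variance)
        except (SampleSizeError, DegenerateFitError) as exc:
            out.warnings.append(f"t-test {organ}: {exc}")
        for prolapsed, tag in ((False, "normal"), (True, "prolapsed")):
            grp = cohort[(cohort["organ"] == organ) & (cohort["prolapse"] == prolapsed)]
            try:
                out.regressions[(organ, tag)] = age_regression(grp)
            except (SampleSizeError, DegenerateFitError) as exc:
                out.warnings.append(f"regression {organ}/{tag}: {exc}")
    try:
        out.anova_prolapse_organ = twoway_anova(
            matched, "mean_collagen_au", "prolapse", "organ"
        )
    except DesignError as exc:
        out.warnings.append(f"ANOVA prolapse x organ: {exc}")
    binned = cohort.copy()
    binned["age_bin"] = (binned["age_months"] // age_bin_months).astype(int)
    for factor, attr in (("prolapse", "anova_age_prolapse"), ("organ", "anova_age_organ")):
        try:
            setattr(out, attr, twoway_anova(
                binned, "mean_collagen_au", "age_bin", factor, interaction=False
            ))
        except DesignError as exc:
            out.warnings.append(f"ANOVA age x {factor}: {exc}")
    return out


def age_ancova(
    cohort: pd.DataFrame, factor: str, response: str = "mean_collagen_au"
) -> AnovaResult:
    """ANCOVA-style alternative: continuous age plus a categorical factor."""
    df = validate_cohort(cohort)
    model = smf.ols(f"{response} ~ age_months + C({factor})", data=df).fit()
    if model.df_resid < 1:
        raise DesignError("saturated design: residual df = 0")
    table = sm.stats.anova_lm(model, typ=2)
    terms = [t for t in table.index if t != "Residual"]
    return AnovaResult(
        factor_names=tuple(terms),
        f_statistics=tuple(float(table.loc[t, "F"]) for t in terms),
        p_values=tuple(float(table.loc[t, "PR(>F)"]) for t in terms),
        df_table=tuple(float(table.loc[t, "df"]) for t in terms),
        residual_df=float(table.loc["Residual", "df"]),
        ss_type="II",
    )


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
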