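"""Hierarchical group statistics for migration-parameter comparisons.

The inferential unit throughout is the cell *line* (the individual donor),
never the cell: per-cell metrics are averaged within line first, and t
tests, two-way ANOVAs (disease status × ECM concentration) with Tukey HSD
post hocs, and concentration–response slope comparisons all operate on one
value per line.  A pooled two-sample t test reconstructed from published
(mean, SEM, n) summaries is provided so printed group summaries can be
re-checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .decay import LinearFitResult, extra_ss_f_test, fit_linear


@dataclass
class GroupSummary:
    """One scalar per line for a factor combination, with mean ± SEM."""

    labels: dict
    line_values: np.ndarray

    def __post_init__(self) -> None:
        self.line_values = np.asarray(self.line_values, dtype=float)
        if len(self.line_values) < 2:
            raise ValueError("need >= 2 lines for a group summary")

    @property
    def n(self) -> int:
        return len(self.line_values)

    @property
    def mean(self) -> float:
        return float(self.line_values.mean())

    @property
    def sem(self) -> float:
        return float(self.line_values.std(ddof=1) / np.sqrt(self.n))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA with Tukey pairwise comparisons.

    ``table`` is the ANOVA table (sum_sq, df, F, PR(>F) per term);
    ``tukey`` the pairwise comparisons over disease×concentration cells.
    """

    f_disease: float
    p_disease: float
    f_concentration: float
    p_concentration: float
    f_interaction: float
    p_interaction: float
    table: pd.DataFrame
    cell_means: pd.DataFrame
    tukey: pd.DataFrame


def pooled_t_from_summary(m1: float, sem1: float, n1: int,
                          m2: float, sem2: float, n2: int) -> TTestResult:
    """Pooled-variance two-sample t test from (mean, SEM, n) summaries.

    Recovers each group SD as SEM·√n, pools the variances, and uses
    df = n1 + n2 - 2 with a two-tailed p.  For n1 = n2 the statistic
    reduces to (m1 - m2)/√(SEM1² + SEM2²).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    s1, s2 = sem1 * np.sqrt(n1), sem2 * np.sqrt(n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    return TTestResult(t=float(t), df=df, p=float(2 * sps.t.sf(abs(t), df)))


def t_from_line_values(values1, values2) -> TTestResult:
    """Classic pooled two-sample t test on raw per-line values.

    Agrees with :func:`pooled_t_from_summary` applied to its own summaries.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("need >= 2 values per group")
    if v1.std() == 0 and v2.std() == 0 and v1.mean() == v2.mean():
        raise ValueError("t statistic undefined: zero variance and equal means")
    res = sps.ttest_ind(v1, v2, equal_var=True)
    return TTestResult(t=float(res.statistic), df=len(v1) + len(v2) - 2,
                       p=float(res.pvalue))


def two_way_anova(values, disease, concentration) -> AnovaResult:
    """Two-way fixed-effects ANOVA of line values on disease × concentration.

    Requires a balanced design with >= 2 lines per cell (unbalanced designs
    are rejected).  Tukey HSD runs over the disease×concentration cell
    means using the studentized range, supporting the patient-vs-control
    within-concentration comparisons.  If every value is identical the
    decomposition is degenerate and all F are reported as 0.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "disease": pd.Categorical(disease),
        "concentration": pd.Categorical(concentration),
    })
    counts = df.groupby(["disease", "concentration"], observed=False).size()
    if (counts < 2).any():
        raise ValueError(f"empty or singleton design cells:\n{counts}")
    if counts.nunique() != 1:
        raise ValueError("unbalanced designs are not supported")

    cell_means = (df.groupby(["disease", "concentration"], observed=False)
                  ["value"].mean().reset_index())
    cell_label = (df["disease"].astype(str) + "|"
                  + df["concentration"].astype(str))

    if np.ptp(df["value"].to_numpy()) == 0.0:
        zeros = pd.DataFrame({"F": [0.0] * 3, "PR(>F)": [1.0] * 3},
                             index=["C(disease)", "C(concentration)",
                                    "C(disease):C(concentration)"])
        tk = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj",
                                   "lower", "upper", "reject"])
        return AnovaResult(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, zeros, cell_means, tk)

    model = smf.ols("value ~ C(disease) * C(concentration)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tuk = pairwise_tukeyhsd(df["value"].to_numpy(), cell_label.to_numpy())
    tukey = pd.DataFrame(tuk.summary().data[1:],
                         columns=tuk.summary().data[0])
    return AnovaResult(
        f_disease=float(table.loc["C(disease)", "F"]),
        p_disease=float(table.loc["C(disease)", "PR(>F)"]),
        f_concentration=float(table.loc["C(concentration)", "F"]),
        p_concentration=float(table.loc["C(concentration)", "PR(>F)"]),
        f_interaction=float(table.loc["C(disease):C(concentration)", "F"]),
        p_interaction=float(table.loc["C(disease):C(concentration)", "PR(>F)"]),
        table=table, cell_means=cell_means, tukey=tukey)


@dataclass
class SlopeCompareResult:
    """Per-group concentration–response lines and the shared-slope F test."""

    fits: dict[str, LinearFitResult]
    f_shared_slope: float
    p_shared_slope: float


def concentration_slope_compare(values, concentration, group) -> SlopeCompareResult:
    """Compare concentration–response slopes between two groups.

    Fits an OLS line of the line-level parameter against concentration per
    group, then tests "one shared slope (separate intercepts)" against
    "separate slopes" with the extra sum-of-squares F test.  A significant
    F means the groups respond to concentration at different rates — e.g.
    a flat patient response against a rising control one.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(concentration, dtype=float)
    g = np.asarray(group)
    names = sorted(set(g.tolist()))
    if len(names) != 2:
        raise ValueError("slope comparison needs exactly 2 groups")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 concentrations")
    fits = {name: fit_linear(x[g == name], y[g == name]) for name in names}
    ind = (g == names[1]).astype(float)
    shared = np.column_stack([x, ind, np.ones_like(x)])
    separate = np.column_stack([x, x * ind, ind, np.ones_like(x)])

    def _rss(design):
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ coef
        return float(r @ r)

    f, p = extra_ss_f_test(_rss(shared), len(y) - 3, _rss(separate), len(y) - 4)
    return SlopeCompareResult(fits=fits, f_shared_slope=f, p_shared_slope=p)
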