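"""Nitrogen-cycling summaries for tank water-chemistry time series.

Continuous analyte measurements per tank are reduced to areas under the
curve (trapezoidal rule, mg*day/L); nitrate AUCs are regressed on a binary
inoculum covariate and the per-tank number of dead fish
(``nitrate ~ inoculum + dead_fish``), with per-term explained variance from
a sequential (Type I) ANOVA on the fitted model. Welch t-tests compare
physicochemical summaries between inoculum arms. Missing days are simply
absent trapezoid nodes — no interpolation or imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "VariancePartition",
    "trapezoid_auc",
    "tank_aucs",
    "fit_nitrate_model",
    "welch_t_test",
    "chemistry_screen",
]


@dataclass
class VariancePartition:
    """Sequential ANOVA decomposition of a fitted linear model."""

    table: pd.DataFrame  # rows: terms + Residual; columns: df, sum_sq, r_squared
    coefficients: pd.Series
    std_errors: pd.Series
    r_squared_total: float
    flags: dict[str, str]

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "r_squared"])


def trapezoid_auc(days: np.ndarray | pd.Series, values: np.ndarray | pd.Series) -> float:
    """Trapezoidal area under a (day, value) series, in mg*day/L."""
    t = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("days and values differ in length")
    if t.size < 2:
        raise ValueError("AUC needs at least 2 points")
    if not (np.diff(t) > 0).all():
        raise ValueError("days must be strictly increasing")
    return float(np.trapezoid(v, t))


def tank_aucs(chemistry: pd.DataFrame, analyte: str = "nitrate") -> pd.Series:
    """Per-tank AUC of one analyte from a long-format chemistry table."""
    sub = chemistry[chemistry["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"analyte {analyte!r} not present in chemistry table")
    out = {}
    for tank, grp in sub.groupby("tank"):
        grp = grp.sort_values("day")
        out[tank] = trapezoid_auc(grp["day"].to_numpy(), grp["value"].to_numpy())
    return pd.Series(out, name=f"auc_{analyte}").sort_index()


def fit_nitrate_model(
    auc_per_tank: pd.Series,
    inoculum: pd.Series,
    dead_fish: pd.Series,
) -> VariancePartition:
    """OLS of nitrate AUC on inoculum (CIT=0, EIT=1) and dead-fish count.

    Sequential ANOVA sums of squares follow the formula order
    (inoculum first, then dead_fish); per-term R-squared is SS over total
    SS. A constant covariate is reported with R-squared 0 and a flag rather
    than failing.
    """
    tanks = auc_per_tank.index
    if len(tanks) < 3:
        raise ValueError("need at least 3 tanks")
    inoc = inoculum.loc[tanks]
    if inoc.dtype == object:
        inoc = inoc.map({"CIT": 0, "EIT": 1})
        if inoc.isna().any():
            raise ValueError("inoculum must be CIT/EIT or binary")
    df = pd.DataFrame(
        {
            "nitrate": auc_per_tank.to_numpy(dtype=float),
            "inoculum": inoc.to_numpy(dtype=float),
            "dead_fish": dead_fish.loc[tanks].to_numpy(dtype=float),
        }
    )
    flags: dict[str, str] = {}
    terms = ["inoculum", "dead_fish"]
    active = [t for t in terms if df[t].nunique() > 1]
    for t in terms:
        if t not in active:
            flags[t] = "constant covariate; R-squared set to 0"
    formula = "nitrate ~ " + " + ".join(active) if active else "nitrate ~ 1"
    fit = smf.ols(formula, data=df).fit()
    total_ss = float(((df["nitrate"] - df["nitrate"].mean()) ** 2).sum())
    rows = []
    if active:
        anova = sm.stats.anova_lm(fit, typ=1)
        for t in terms:
            if t in active:
                ss = float(anova.loc[t, "sum_sq"])
                rows.append({"term": t, "df": float(anova.loc[t, "df"]), "sum_sq": ss,
                             "r_squared": ss / total_ss if total_ss > 0 else 0.0})
            else:
                rows.append({"term": t, "df": 0.0, "sum_sq": 0.0, "r_squared": 0.0})
        resid_ss = float(anova.loc["Residual", "sum_sq"])
        resid_df = float(anova.loc["Residual", "df"])
    else:
        for t in terms:
            rows.append({"term": t, "df": 0.0, "sum_sq": 0.0, "r_squared": 0.0})
        resid_ss, resid_df = total_ss, float(len(df) - 1)
    rows.append({"term": "Residual", "df": resid_df, "sum_sq": resid_ss,
                 "r_squared": resid_ss / total_ss if total_ss > 0 else 1.0})
    table = pd.DataFrame(rows).set_index("term")
    return VariancePartition(
        table=table,
        coefficients=fit.params,
        std_errors=fit.bse,
        r_squared_total=float(fit.rsquared),
        flags=flags,
    )


def welch_t_test(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite df; two-sided p.

    Requires two values per group and non-degenerate variance.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chemistry_screen(
    chemistry: pd.DataFrame,
    inoculum_by_tank: pd.Series,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-analyte Welch t-tests of CIT vs EIT per-tank summaries.

    Each tank's repeated measures are reduced to a time summary (``mean``
    over observed days, or ``auc``); one test runs per analyte, with no
    multiplicity correction (individual tests are reported).
    """
    if summary not in ("mean", "auc"):
        raise ValueError("summary must be 'mean' or 'auc'")
    rows = []
    for analyte, sub in chemistry.groupby("analyte"):
        if summary == "mean":
            per_tank = sub.groupby("tank")["value"].mean()
        else:
            per_tank = tank_aucs(chemistry, analyte)
        labels = inoculum_by_tank.loc[per_tank.index]
        t, df, p = welch_t_test(per_tank[labels == "CIT"], per_tank[labels == "EIT"])
        rows.append({"analyte": analyte, "t": t, "df": df, "p_value": p})
    return pd.DataFrame(rows).set_index("analyte")
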