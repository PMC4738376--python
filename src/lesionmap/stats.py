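"""Tabular statistics battery for the behavioural data.

Covers the non-imaging analyses: descriptive summaries (median, IQR,
range), Kendall tau-b correlations, Wilcoxon signed-rank effect sizes
r = Z/sqrt(N) for the baseline-to-outcome change, multiple regression of
the change score on tract lesion load plus nuisance covariates (with
standardized coefficients and partial correlations), and proportional-odds
ordinal regression for the Functional Ambulation Category, whose six
levels make a linear model inappropriate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .volumes import MEASURES, LesionCohort


class DegenerateDataError(ValueError):
    """Input without enough variation to support the requested statistic."""


# ---------------------------------------------------------------------------
# correlation and paired-change statistics


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with a two-sided p value.

    Exact p by pair enumeration when n <= 50 and no ties are present,
    otherwise the normal approximation.  All-tied input in either variable
    leaves tau undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("tau undefined: a variable is constant")
    has_ties = np.unique(x).size < len(x) or np.unique(y).size < len(y)
    method = "exact" if (len(x) <= 50 and not has_ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_effect(baseline, outcome) -> dict:
    """Wilcoxon signed-rank test on outcome - baseline with effect size
    r = |Z| / sqrt(N).

    Zero differences are dropped and ties receive average ranks; N is the
    number of pairs actually entering the test.  All-zero differences
    leave no test and raise.
    """
    baseline = np.asarray(baseline, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if len(baseline) != len(outcome) or len(baseline) < 5:
        raise ValueError("need >= 5 paired observations")
    diff = outcome - baseline
    n_nonzero = int(np.sum(diff != 0))
    if n_nonzero == 0:
        raise DegenerateDataError("all differences are zero: no test")
    d = diff[diff != 0]
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False,
                       method="approx")
    # scipy's zstatistic is computed from min(W+, W-); fix the sign so
    # positive Z means outcome exceeds baseline
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = len(d) * (len(d) + 1) / 4
    z = float(np.copysign(abs(res.zstatistic), w_plus - mu))
    return {
        "statistic": float(res.statistic),
        "z": z,
        "n": n_nonzero,
        "effect_r": abs(z) / np.sqrt(n_nonzero),
        "p": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# regression battery


@dataclass
class RegressionResult:
    """OLS table in the layout of the multiple-regression analyses:
    per-predictor raw beta, SE, standardized beta, partial correlation,
    two-sided p and the raw bivariate Pearson r with the response."""

    table: pd.DataFrame          # indexed by predictor
    r_squared: float
    df_resid: int
    nobs: int


def fit_linear(change, predictors: pd.DataFrame) -> RegressionResult:
    """Multiple regression of a change score on the given predictors.

    Ordinal covariates (Fazekas 0-3, baseline FAC) enter as numeric
    scores.  ``std_beta`` rescales each beta by sd(x)/sd(y); the partial
    correlation is recovered from the coefficient t as t/sqrt(t^2 + df).
    """
    y = np.asarray(change, dtype=float)
    X = predictors.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few observations for the number of predictors")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear columns {worst}")
    fit = sm.OLS(y, design).fit()
    df = int(fit.df_resid)
    sd_y = np.std(y, ddof=1)
    rows = {}
    for name in X.columns:
        beta = fit.params[name]
        t = fit.tvalues[name]
        rows[name] = {
            "beta": beta,
            "se": fit.bse[name],
            "std_beta": beta * np.std(X[name], ddof=1) / sd_y,
            "partial_r": t / np.sqrt(t**2 + df),
            "p": fit.pvalues[name],
            "pearson_r": np.corrcoef(X[name], y)[0, 1],
        }
    return RegressionResult(table=pd.DataFrame(rows).T,
                            r_squared=float(fit.rsquared),
                            df_resid=df, nobs=int(fit.nobs))


@dataclass
class OrdinalResult:
    """Proportional-odds table: per-predictor odds ratio, 95% CI, Wald
    chi-square (1 df), p, and raw Pearson r with the response."""

    table: pd.DataFrame
    converged: bool
    nobs: int
    llf: float


def fit_ordinal(change, predictors: pd.DataFrame) -> OrdinalResult:
    """Cumulative-logit (proportional-odds) regression of an ordinal
    change score.

    Per predictor: OR = exp(coef), Wald chi2 = (coef/se)^2, 95% CI =
    exp(coef +/- 1.96 se).  The model is parameterised so that OR < 1
    means the predictor lowers the odds of a larger improvement.
    Non-convergence or separation is flagged rather than silently
    reported.
    """
    y = pd.Series(np.asarray(change, dtype=float))
    X = predictors.astype(float).reset_index(drop=True)
    if y.nunique() < 3:
        raise DegenerateDataError(
            f"ordinal response has {y.nunique()} categories; need >= 3")
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", maxiter=200, disp=False)
    converged = bool(fit.mle_retvals.get("converged", False))
    rows = {}
    for name in X.columns:
        coef = fit.params[name]
        se = fit.bse[name]
        wald = (coef / se) ** 2
        rows[name] = {
            "odds_ratio": np.exp(coef),
            "ci_low": np.exp(coef - 1.96 * se),
            "ci_high": np.exp(coef + 1.96 * se),
            "wald_chi2": wald,
            "p": 2 * sps.norm.sf(np.abs(coef / se)),
            "pearson_r": np.corrcoef(X[name], y)[0, 1],
        }
        if not np.isfinite(se) or se > 50:
            raise DegenerateDataError(
                f"likely separation: unstable standard error for {name}")
    return OrdinalResult(table=pd.DataFrame(rows).T, converged=converged,
                         nobs=int(fit.nobs), llf=float(fit.llf))


def load_regression_battery(cohort: LesionCohort, loads: pd.DataFrame
                            ) -> dict[str, RegressionResult | OrdinalResult]:
    """The per-measure tract-load battery: change ~ wcst_ll + age +
    fazekas + baseline + time, multiple regression for walk speed and
    MRMI, ordinal regression for FAC.  Subjects flagged outside the tract
    support are excluded, not zero-filled."""
    tbl = cohort.table().merge(loads, on="subject_id")
    ok = tbl[tbl["status"] == "ok"].reset_index(drop=True)
    results: dict[str, RegressionResult | OrdinalResult] = {}
    for measure in MEASURES:
        X = pd.DataFrame({
            "wcst_ll": ok["wcst_ll_cm3"],
            "age": ok["age"],
            "fazekas": ok["fazekas"],
            "baseline": ok[f"{measure}_baseline"],
            "time": ok["time_days"],
        })
        y = ok[f"{measure}_change"]
        if measure == "fac":
            results[measure] = fit_ordinal(y, X)
        else:
            results[measure] = fit_linear(y, X)
    return results


# ---------------------------------------------------------------------------
# descriptive summaries


def _summary_row(values: np.ndarray) -> dict:
    # linear-interpolation quantile convention, stated once and kept fixed
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "median": med, "iqr_low": q1, "iqr_high": q3,
        "min": float(np.min(values)), "max": float(np.max(values)),
        "mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1)),
    }


def summarize_cohort(cohort: LesionCohort) -> dict[str, pd.DataFrame]:
    """Descriptive tables: demographics/covariates, and per-measure
    baseline/outcome/change summaries with Wilcoxon effect sizes."""
    tbl = cohort.table()
    demo = pd.DataFrame({
        name: _summary_row(tbl[name].to_numpy(dtype=float))
        for name in ("age", "fazekas", "time_days", "lesion_volume_cm3")
    }).T

    rows = {}
    for m in MEASURES:
        base = tbl[f"{m}_baseline"].to_numpy(dtype=float)
        out = tbl[f"{m}_outcome"].to_numpy(dtype=float)
        row = {}
        for stage, vals in (("baseline", base), ("outcome", out),
                            ("change", out - base)):
            s = _summary_row(vals)
            row[f"{stage}_median"] = s["median"]
            row[f"{stage}_iqr_low"] = s["iqr_low"]
            row[f"{stage}_iqr_high"] = s["iqr_high"]
        try:
            eff = wilcoxon_effect(base, out)
            row["effect_r"] = eff["effect_r"]
            row["p"] = eff["p"]
        except DegenerateDataError:
            row["effect_r"] = np.nan
            row["p"] = np.nan
        rows[m] = row
    return {"covariates": demo, "measures": pd.DataFrame(rows).T}


def covariate_correlations(cohort: LesionCohort) -> pd.DataFrame:
    """Kendall tau-b of each measure's change score with age, Fazekas,
    baseline score and time to baseline (no multiplicity correction: the
    table is descriptive)."""
    tbl = cohort.table()
    rows = {}
    for m in MEASURES:
        change = tbl[f"{m}_change"]
        row = {}
        for label, col in (("age", "age"), ("fazekas", "fazekas"),
                           ("baseline", f"{m}_baseline"), ("time", "time_days")):
            try:
                tau, p = kendall_tau(tbl[col], change)
            except DegenerateDataError:
                tau, p = np.nan, np.nan
            row[f"tau_{label}"] = tau
            row[f"p_{label}"] = p
        rows[m] = row
    return pd.DataFrame(rows).T
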