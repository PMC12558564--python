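"""Cognitive classification and the study's statistical toolkit.

Cognitive impairment is classified from MMSE with Singapore education-adjusted
cut-offs (no formal education <=25, primary <=27, secondary or higher <=29).
The statistics mirror a small-cohort observational analysis: Pearson r with
Fisher-z 95% CIs, simple and covariate-adjusted OLS with both raw and
standardized coefficients, one-way ANOVA, Mann-Whitney U, Cohen's d and
stratum mean differences with Welch intervals. Engines are scipy/statsmodels;
alpha = .05 two-sided throughout, with no multiplicity adjustment (a
Benjamini-Hochberg column is emitted for transparency where p-value tables
are produced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm

#: education-adjusted MMSE cut-offs: CI iff mmse <= cutoff
MMSE_CUTOFFS = {"none": 25, "primary": 27, "secondary_plus": 29}

EDUCATION_LEVELS = ("none", "primary", "secondary_plus")


@dataclass
class StatResult:
    """An estimate with its interval, test statistic and p-value."""

    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    statistic: float = float("nan")
    p_value: float = float("nan")
    n: int | tuple = 0
    r_squared: float = float("nan")
    adj_r_squared: float = float("nan")
    extra: dict = field(default_factory=dict)


def classify_cognition(education: str, mmse: int) -> str:
    """'CI' iff the MMSE score is at or below the education-adjusted cut-off.

    Cut-offs: no formal education 25, primary 27, secondary or higher 29.
    """
    if education not in MMSE_CUTOFFS:
        raise ValueError(f"unknown education level {education!r}; "
                         f"expected one of {sorted(MMSE_CUTOFFS)}")
    if not (0 <= mmse <= 30):
        raise ValueError(f"MMSE must be in [0, 30], got {mmse}")
    return "CI" if mmse <= MMSE_CUTOFFS[education] else "nonCI"


def pearson_r_ci(x, y, alpha: float = 0.05) -> StatResult:
    """Pearson correlation with Fisher-z 95% CI and t-distribution p-value.

    The CI uses the z-transform with standard error 1/sqrt(n-3); the two-sided
    p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sp_stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zcrit = sp_stats.norm.ppf(1 - alpha / 2)
    half = zcrit / np.sqrt(n - 3)
    t_stat = r * np.sqrt((n - 2) / max(1e-300, 1 - r * r))
    return StatResult(estimate=float(r), ci_low=float(np.tanh(z - half)),
                      ci_high=float(np.tanh(z + half)), statistic=float(t_stat),
                      p_value=float(p), n=n)


def fit_linear(outcome, predictor, covariates: pd.DataFrame | None = None,
               alpha: float = 0.05, robust: bool = False) -> StatResult:
    """OLS of outcome on predictor (plus optional covariates), with intercept.

    ``estimate`` is the raw slope (outcome units per predictor unit, e.g. m/s
    of DGS per GPR unit) with its t-based CI and p; ``extra['std_beta']`` is
    the coefficient refit on z-scored outcome and predictor (continuous
    covariates z-scored too), which equals Pearson r in the simple model.
    ``robust=True`` switches the interval and p-value to HC3
    heteroscedasticity-robust standard errors — appropriate when the
    observations are participant-level means pooled over unequal numbers of
    bouts. Rank-deficient designs are rejected with the offending column
    named.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    X = pd.DataFrame({"predictor": x})
    if covariates is not None and len(covariates.columns) > 0:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    n, k = len(y), X.shape[1] + 1
    if n <= k + 1:
        raise ValueError("too few observations for the number of coefficients")
    Xc = sm.add_constant(X.astype(float))
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        for col in X.columns:
            rest = Xc.drop(columns=[col])
            if np.linalg.matrix_rank(rest.to_numpy()) == rank:
                raise ValueError(f"design is rank deficient: column {col!r} "
                                 "is collinear with the others")
        raise ValueError("design is rank deficient")
    fit = sm.OLS(y, Xc).fit()
    if robust:
        fit = sm.OLS(y, Xc).fit(cov_type="HC3")
    ci = fit.conf_int(alpha=alpha).loc["predictor"]

    def _z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    Xs = pd.DataFrame({"predictor": _z(x)})
    if covariates is not None and len(covariates.columns) > 0:
        for col in covariates.columns:
            v = covariates[col].to_numpy(dtype=float)
            # indicator columns stay on their 0/1 coding
            Xs[col] = v if set(np.unique(v)) <= {0.0, 1.0} else _z(v)
    std_fit = sm.OLS(_z(y), sm.add_constant(Xs)).fit()
    return StatResult(
        estimate=float(fit.params["predictor"]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        statistic=float(fit.tvalues["predictor"]),
        p_value=float(fit.pvalues["predictor"]), n=n,
        r_squared=float(fit.rsquared), adj_r_squared=float(fit.rsquared_adj),
        extra={"std_beta": float(std_fit.params["predictor"]),
               "intercept": float(fit.params["const"])},
    )


def oneway_anova(groups: list) -> StatResult:
    """One-way ANOVA F test across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    f, p = sp_stats.f_oneway(*groups)
    return StatResult(estimate=float(f), statistic=float(f), p_value=float(p),
                      n=tuple(len(g) for g in groups))


def mann_whitney_u(x, y) -> StatResult:
    """Mann-Whitney U, minimum-U convention.

    Exact null distribution when n_x * n_y <= 400 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                use_continuity=True)
    u1 = float(res.statistic)
    u_min = min(u1, len(x) * len(y) - u1)
    return StatResult(estimate=u_min, statistic=u_min, p_value=float(res.pvalue),
                      n=(len(x), len(y)), extra={"method": method, "u1": u1})


def cohens_d(x, y) -> float:
    """(mean_x - mean_y) / pooled SD, pooled with n-1 weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def stratum_mean_difference(dgs_a, dgs_b, alpha: float = 0.05) -> StatResult:
    """nonCI-minus-CI mean DGS difference within a matched stratum.

    With per-track (or per-cell) sample vectors, a Welch t interval and
    p-value are attached and Cohen's d is reported in ``extra``; with bare
    stratum means (scalars) only the difference is returned.
    """
    a = np.atleast_1d(np.asarray(dgs_a, dtype=float))
    b = np.atleast_1d(np.asarray(dgs_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("stratum absent in one group")
    diff = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return StatResult(estimate=diff, n=(a.size, b.size))
    t, p = sp_stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    half = sp_stats.t.ppf(1 - alpha / 2, df) * np.sqrt(va + vb)
    return StatResult(estimate=diff, ci_low=diff - half, ci_high=diff + half,
                      statistic=float(t), p_value=float(p),
                      n=(a.size, b.size),
                      extra={"cohen_d": cohens_d(a, b), "welch_df": float(df)})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (emitted for transparency only)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def weighted_mean(values, weights) -> float:
    """Duration-weighted mean; the pooling used for group-level DGS."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    return float(np.sum(values * weights) / np.sum(weights))


def gpr_regression(cells: pd.DataFrame, group: str,
                   covariates: pd.DataFrame | None = None,
                   alpha: float = 0.05) -> StatResult:
    """GPR-vs-DGS regression for one cognitive group.

    ``cells`` holds per-(participant, stratum) mean DGS with columns
    group, gpr, mean_dgs (optionally age, sex, education for adjustment).
    """
    sub = cells[cells["group"] == group]
    if len(sub) < 5:
        raise ValueError(f"too few cells for group {group!r}")
    return fit_linear(sub["mean_dgs"], sub["gpr"], covariates=covariates, alpha=alpha)


def covariate_design(cells: pd.DataFrame) -> pd.DataFrame:
    """Age/sex/education design columns (reference: female, no education)."""
    return pd.DataFrame({
        "age": cells["age"].to_numpy(dtype=float),
        "sex_male": (cells["sex"] == "male").astype(float).to_numpy(),
        "edu_primary": (cells["education"] == "primary").astype(float).to_numpy(),
        "edu_secondary_plus": (cells["education"] == "secondary_plus")
                              .astype(float).to_numpy(),
    })


def make_report(cohort: pd.DataFrame, cells: pd.DataFrame,
                exposure_tables: dict[str, pd.DataFrame] | None = None,
                alpha: float = 0.05, adjust: bool = False) -> dict[str, pd.DataFrame]:
    """Assemble the demographics / association / stratified report tables.

    ``cohort``: one row per participant (id, age, sex, education, mmse, group,
    dgs). ``cells``: per-(participant, stratum) mean DGS with gpr, land_use,
    seconds columns. Returns a dict of DataFrames:

    - ``demographics``: group-wise cohort summary
    - ``associations``: per-group mean DGS, GPR slope (raw + standardized),
      Pearson r, ANOVA F across GPR strata
    - ``strata``: per-stratum group means, differences, Welch CI, Cohen's d,
      Mann-Whitney p for time spent, with a BH-adjusted column
    """
    out: dict[str, pd.DataFrame] = {}

    demo_rows = []
    for grp, sub in cohort.groupby("group"):
        demo_rows.append({
            "group": grp, "n": len(sub),
            "age_mean": sub["age"].mean(), "age_sd": sub["age"].std(ddof=1),
            "female_pct": 100.0 * (sub["sex"] == "female").mean(),
            "mmse_mean": sub["mmse"].mean(), "mmse_sd": sub["mmse"].std(ddof=1),
            "dgs_mean": sub["dgs"].mean(), "dgs_sd": sub["dgs"].std(ddof=1),
        })
    out["demographics"] = pd.DataFrame(demo_rows)

    assoc_rows = []
    for grp in ("nonCI", "CI"):
        sub = cells[cells["group"] == grp]
        if len(sub) < 5 or sub["gpr"].nunique() < 2:
            assoc_rows.append({"group": grp, "missing": True})
            continue
        cov = None
        if adjust:
            cov = covariate_design(sub)
        reg = gpr_regression(cells, grp, covariates=cov, alpha=alpha)
        r = pearson_r_ci(sub["gpr"], sub["mean_dgs"], alpha=alpha)
        groups_by_gpr = [g["mean_dgs"].to_numpy() for _, g in sub.groupby("gpr")
                         if len(g) >= 2]
        anova = (oneway_anova(groups_by_gpr) if len(groups_by_gpr) >= 2
                 else StatResult(estimate=float("nan")))
        gsub = cohort[cohort["group"] == grp]
        assoc_rows.append({
            "group": grp, "missing": False, "n_cells": len(sub),
            "dgs_mean": gsub["dgs"].mean(), "dgs_sd": gsub["dgs"].std(ddof=1),
            "beta_raw": reg.estimate, "beta_std": reg.extra["std_beta"],
            "beta_ci_low": reg.ci_low, "beta_ci_high": reg.ci_high,
            "beta_p": reg.p_value, "r": r.estimate, "r_ci_low": r.ci_low,
            "r_ci_high": r.ci_high, "r_p": r.p_value,
            "anova_f": anova.estimate, "anova_p": anova.p_value,
            "r_squared": reg.r_squared, "adj_r_squared": reg.adj_r_squared,
        })
    out["associations"] = pd.DataFrame(assoc_rows)

    strat_rows = []
    for by in ("gpr", "land_use"):
        for stratum, sub in cells.groupby(by):
            a = sub.loc[sub["group"] == "nonCI", "mean_dgs"].to_numpy()
            b = sub.loc[sub["group"] == "CI", "mean_dgs"].to_numpy()
            row = {"stratum_type": by, "stratum": stratum,
                   "mean_dgs_nonCI": a.mean() if a.size else float("nan"),
                   "mean_dgs_CI": b.mean() if b.size else float("nan"),
                   "n_nonCI": a.size, "n_CI": b.size}
            if a.size and b.size:
                d = stratum_mean_difference(a, b, alpha=alpha)
                row.update(diff=d.estimate, diff_ci_low=d.ci_low,
                           diff_ci_high=d.ci_high, diff_p=d.p_value,
                           cohen_d=d.extra.get("cohen_d", float("nan")))
                sa = sub.loc[sub["group"] == "nonCI", "seconds"].to_numpy()
                sb = sub.loc[sub["group"] == "CI", "seconds"].to_numpy()
                if sa.size and sb.size:
                    mw = mann_whitney_u(sa, sb)
                    row["time_mw_p"] = mw.p_value
            strat_rows.append(row)
    strata = pd.DataFrame(strat_rows)
    if "diff_p" in strata.columns:
        mask = strata["diff_p"].notna()
        strata.loc[mask, "diff_p_bh"] = bh_adjust(strata.loc[mask, "diff_p"])
    out["strata"] = strata

    if exposure_tables:
        out.update(exposure_tables)
    return out
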