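"""Correlation, group-comparison and survival stages of the asymmetry analysis.

Thin, contract-stable wrappers over scipy and lifelines: pairwise-complete
Pearson correlations between the topological asymmetry measures and the other
cohort variables; t-test / one-way ANOVA / chi-square group comparisons; and
Cox proportional-hazards fits in unadjusted and confounder-adjusted variants
with fixed reference levels (men, the Vis sub-cohort, no multiple
asymmetries).  No multiple-testing correction is applied by default; an
optional Benjamini-Hochberg adjustment can be switched on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "correlation_matrix",
    "cox_fit",
    "group_tests",
]


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int


def correlation_matrix(
    table: pd.DataFrame,
    x_vars: list[str],
    y_vars: list[str],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations, one row per (x, y) pair.

    Requires >= 3 complete pairs per correlation; a constant series gives a
    missing r with a warning.  ``adjust="bh"`` appends Benjamini-Hochberg
    adjusted p-values (off by default).
    """
    rows = []
    for x in x_vars:
        for y in y_vars:
            pair = table[[x]] if x == y else table[[x, y]]
            pair = pair.dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({x}, {y})")
            xv = pair[x].to_numpy(float)
            yv = xv if x == y else pair[y].to_numpy(float)
            if xv.std() == 0 or yv.std() == 0:
                warnings.warn(f"constant series in ({x}, {y}); correlation undefined", stacklevel=2)
                rows.append(CorrelationResult(x, y, np.nan, np.nan, n))
                continue
            r, p = sps.pearsonr(xv, yv)
            rows.append(CorrelationResult(x, y, float(r), float(p), n))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if adjust == "bh" and not out.empty:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


#: categorical covariates and their reference levels for the survival model
REFERENCE_LEVELS = {"sex": "male", "cohort": "Vis", "multi_asymmetry": False}


def _design(records: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with fixed reference levels for categorical covariates."""
    cols = {}
    names = []
    for cov in covariates:
        ser = records[cov]
        if cov in REFERENCE_LEVELS or ser.dtype == object or ser.dtype == bool:
            ref = REFERENCE_LEVELS.get(cov, None)
            levels = [lv for lv in pd.unique(ser.dropna())]
            if ref is not None and ref in levels:
                levels = [ref] + sorted((lv for lv in levels if lv != ref), key=str)
            else:
                levels = sorted(levels, key=str)
            for lv in levels[1:]:
                name = f"{cov}[{lv}]"
                cols[name] = (ser == lv).astype(float)
                names.append(name)
        else:
            cols[cov] = ser.astype(float)
            names.append(cov)
    return pd.DataFrame(cols, index=records.index), names


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_years",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; hazard ratios with 95% CI and p per covariate.

    Partial-likelihood estimation is delegated to lifelines.  Categorical
    covariates are expanded against fixed reference levels (men, Vis cohort,
    no multiple asymmetries).  Rows with any missing entry are dropped
    (listwise deletion) with a warning stating the count; >= 10 events are
    required after deletion.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = [duration_col, event_col] + covariates
    data = records[cols].copy()
    n0 = len(data)
    data = data.dropna()
    if len(data) < n0:
        warnings.warn(f"listwise deletion dropped {n0 - len(data)} of {n0} records", stacklevel=2)
    n_events = int(data[event_col].sum())
    if n_events < 10:
        raise ValueError(f"need >= 10 events for a Cox fit, got {n_events}")
    design, names = _design(data, covariates)
    frame = pd.concat([data[[duration_col, event_col]], design], axis=1)

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": names,
            "coef": summary.loc[names, "coef"].to_numpy(),
            "hr": summary.loc[names, "exp(coef)"].to_numpy(),
            "hr_ci_low": summary.loc[names, "exp(coef) lower 95%"].to_numpy(),
            "hr_ci_high": summary.loc[names, "exp(coef) upper 95%"].to_numpy(),
            "p": summary.loc[names, "p"].to_numpy(),
        }
    )
    out.attrs["n"] = len(frame)
    out.attrs["n_events"] = n_events
    return out


@dataclass(frozen=True)
class GroupTestResult:
    variable: str
    test: str          # "t", "anova" or "chi2"
    statistic: float
    p: float
    detail: dict


def group_tests(
    table: pd.DataFrame,
    variable: str,
    by: str,
) -> GroupTestResult:
    """Two-sided comparison of one variable across groups.

    Numeric variables use Welch's t-test for two groups and one-way ANOVA for
    more; categorical variables use the chi-square test on the contingency
    table (expected counts reported in ``detail``).  Empty groups raise an
    error naming the group.
    """
    grouped = table[[variable, by]].dropna().groupby(by, observed=True)
    sizes = grouped.size()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) too small for {by}: {small}")
    if pd.api.types.is_numeric_dtype(table[variable]) and table[variable].nunique() > 5:
        samples = [g[variable].to_numpy(float) for _, g in grouped]
        if len(samples) == 2:
            stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=False)
            test = "t"
        else:
            stat, p = sps.f_oneway(*samples)
            test = "anova"
        detail = {
            "group_means": {k: float(g[variable].mean()) for k, g in grouped},
            "group_sd": {k: float(g[variable].std()) for k, g in grouped},
            "n": sizes.to_dict(),
        }
    else:
        contingency = pd.crosstab(table[variable], table[by])
        stat, p, dof, expected = sps.chi2_contingency(contingency)
        test = "chi2"
        detail = {
            "contingency": contingency,
            "dof": int(dof),
            "expected": pd.DataFrame(expected, index=contingency.index, columns=contingency.columns),
        }
    return GroupTestResult(variable=variable, test=test, statistic=float(stat), p=float(p), detail=detail)
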