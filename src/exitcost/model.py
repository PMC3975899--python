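"""Weighted descriptives and log-linear group-contrast regression.

Two reporting products:

* group summaries — survey-weighted mean, SD and median of annual income,
  welfare and tax by labour-force/condition group (the descriptive table);
* adjusted group effects — OLS on log-transformed outcomes with categorical
  dummies for group, age group, sex and education (main effects only, no
  interactions), reference group full-time employed with no chronic
  condition. A log-scale coefficient beta is reported as the percent
  difference (exp(beta) - 1) * 100 with a 1.96-normal 95% CI.

The weighted median convention is the smallest observed value whose
cumulative weight reaches half the total weight. Outcomes with legitimate
zeros (welfare, tax) are shifted by a small offset before logging; survey
weights enter the descriptives and national totals but the regression is
unweighted by default (a weighted-least-squares switch is provided).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .categories import (
    AGE_GROUPS,
    EDUCATION_LEVELS,
    FT_NO_CONDITION,
    GROUPS,
    REPORTED_GROUPS,
    SEXES,
)

__all__ = [
    "summarize_by_group",
    "weighted_mean",
    "weighted_sd",
    "weighted_median",
    "fit_log_model",
    "LogLinearFit",
    "percent_difference",
    "group_effects",
    "diagnostics",
    "ResidualDiagnostics",
]

#: Normal 95% CI multiplier (large-sample convention).
Z_95 = 1.96

_CANONICAL_LEVELS = {
    "group": list(GROUPS),
    "age_group": list(AGE_GROUPS),
    "sex": list(SEXES),
    "education": list(EDUCATION_LEVELS),
}


# -- weighted descriptives --------------------------------------------------


def weighted_mean(values, weights) -> float:
    y, w = np.asarray(values, float), np.asarray(weights, float)
    return float(np.sum(w * y) / np.sum(w))


def weighted_sd(values, weights) -> float:
    """Weight-frequency (population) standard deviation."""
    y, w = np.asarray(values, float), np.asarray(weights, float)
    m = np.sum(w * y) / np.sum(w)
    return float(np.sqrt(np.sum(w * (y - m) ** 2) / np.sum(w)))


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight is >= half the total weight."""
    y, w = np.asarray(values, float), np.asarray(weights, float)
    order = np.argsort(y, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(y[order][idx])


def summarize_by_group(
    data: pd.DataFrame,
    weight_col: str = "weight",
    value_cols: Sequence[str] = ("income", "welfare", "tax"),
    group_col: str = "group",
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Survey-weighted descriptive table by group.

    One row per group, in the conventional reporting order (the five headline
    groups first), with unweighted n, weighted N and mean/SD/median per
    outcome. Empty groups are omitted with a warning.
    """
    import warnings

    if (data[weight_col] <= 0).any():
        raise ValueError("all weights must be strictly positive")
    if groups is None:
        present = set(data[group_col].unique())
        groups = [g for g in GROUPS if g in present]
        groups += [g for g in sorted(present) if g not in GROUPS]
    rows = []
    for g in groups:
        sub = data[data[group_col] == g]
        if sub.empty:
            warnings.warn(f"group {g!r} has no records; omitted from summary")
            continue
        w = sub[weight_col]
        row = {"group": g, "n": len(sub), "weighted_n": float(w.sum())}
        for col in value_cols:
            row[f"{col}_mean"] = weighted_mean(sub[col], w)
            row[f"{col}_sd"] = weighted_sd(sub[col], w)
            row[f"{col}_median"] = weighted_median(sub[col], w)
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# -- log-linear regression --------------------------------------------------


def _levels_for(data: pd.DataFrame, var: str, reference: str | None = None) -> list:
    present = list(pd.unique(data[var]))
    canonical = _CANONICAL_LEVELS.get(var)
    if canonical is not None:
        levels = [v for v in canonical if v in present]
        levels += [v for v in present if v not in canonical]
    else:
        levels = sorted(present)
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from {var!r}")
        levels = [reference] + [v for v in levels if v != reference]
    return levels


def _design(
    data: pd.DataFrame, levels: Mapping[str, list]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded dummies (first level of each var is ref)."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for var, lv in levels.items():
        for level in lv[1:]:
            cols.append((data[var] == level).to_numpy(float))
            names.append(f"{var}[{level}]")
    return np.column_stack(cols), names


@dataclasses.dataclass
class LogLinearFit:
    """A fitted log-outcome regression with its design metadata."""

    results: "sm.regression.linear_model.RegressionResultsWrapper"
    outcome: str
    offset: float
    levels: dict[str, list]
    param_names: list[str]

    @property
    def reference_group(self) -> str:
        return self.levels["group"][0]

    def coefficient(self, var: str, level) -> tuple[float, float, float]:
        """(beta, se, p-value) for one non-reference dummy."""
        name = f"{var}[{level}]"
        i = self.param_names.index(name)
        return (
            float(self.results.params[i]),
            float(self.results.bse[i]),
            float(self.results.pvalues[i]),
        )

    def predict_median(self, new_data: pd.DataFrame) -> np.ndarray:
        """Median-scale prediction exp(x beta) - offset for new records."""
        for var, lv in self.levels.items():
            unseen = set(new_data[var].unique()) - set(lv)
            if unseen:
                raise ValueError(f"unseen level(s) {unseen} for {var!r}")
        x, _ = _design(new_data, self.levels)
        return np.exp(x @ np.asarray(self.results.params)) - self.offset


def fit_log_model(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("group", "age_group", "sex", "education"),
    offset: float = 0.0,
    weights: Sequence[float] | None = None,
    reference: str = FT_NO_CONDITION,
) -> LogLinearFit:
    """OLS of log(outcome + offset) on categorical main effects.

    ``covariates`` must include ``group``; its reference level is
    ``reference``, other variables use their canonical first category. Pass
    ``weights`` for weighted least squares. Raises on non-positive shifted
    outcomes and on collinear designs (naming the aliased columns).
    """
    if "group" not in covariates:
        raise ValueError("covariates must include 'group'")
    if data["group"].nunique() < 2:
        raise ValueError("need at least two groups to estimate contrasts")
    shifted = data[outcome].to_numpy(float) + offset
    if np.any(shifted <= 0):
        raise ValueError(
            f"log transform needs {outcome} + {offset} > 0 for every record "
            f"(min {shifted.min():.6g}); increase the offset"
        )
    y = np.log(shifted)
    levels = {}
    for var in covariates:
        levels[var] = _levels_for(data, var, reference if var == "group" else None)
    x, names = _design(data, levels)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        r = np.linalg.qr(x, mode="r")
        aliased = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-8 * len(x)]
        raise ValueError(f"collinear design; aliased column(s): {aliased}")
    if weights is None:
        results = sm.OLS(y, x).fit()
    else:
        results = sm.WLS(y, x, weights=np.asarray(weights, float)).fit()
    return LogLinearFit(
        results=results, outcome=outcome, offset=offset, levels=levels, param_names=names
    )


def percent_difference(beta: float, se: float = 0.0) -> tuple[float, tuple[float, float]]:
    """Percent difference and 95% CI implied by a log-scale coefficient.

    Point estimate (exp(beta) - 1) * 100; CI endpoints from beta +/- 1.96 se.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    point = (np.exp(beta) - 1.0) * 100.0
    lo = (np.exp(beta - Z_95 * se) - 1.0) * 100.0
    hi = (np.exp(beta + Z_95 * se) - 1.0) * 100.0
    return float(point), (float(lo), float(hi))


def group_effects(fit: LogLinearFit) -> pd.DataFrame:
    """Adjusted percent differences vs the reference group, with CIs.

    One row per non-reference group: percent difference, 95% CI and two-sided
    p-value for the outcome the model was fitted on.
    """
    rows = []
    for g in fit.levels["group"][1:]:
        beta, se, p = fit.coefficient("group", g)
        point, (lo, hi) = percent_difference(beta, se)
        rows.append(
            {
                "group": g,
                "pct_diff": point,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
                "beta": beta,
                "se": se,
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["outcome"] = fit.outcome
    out.attrs["reference"] = fit.reference_group
    return out


# -- diagnostics ------------------------------------------------------------


@dataclasses.dataclass
class ResidualDiagnostics:
    """Advisory residual checks for a fitted log-linear model."""

    n: int
    degenerate: bool  # essentially zero residual variance
    normality_stat: float
    normality_p: float
    het_stat: float  # Breusch-Pagan LM statistic
    het_p: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def diagnostics(fit: LogLinearFit) -> ResidualDiagnostics:
    """Residual normality (D'Agostino) and heteroscedasticity (Breusch-Pagan).

    Advisory only: the statistics are reported, nothing is enforced. A
    perfect fit (zero residual variance) is flagged degenerate and the tests
    are skipped.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = np.asarray(fit.results.resid, float)
    n = resid.size
    order = np.sort(resid)
    probs = (np.arange(1, n + 1) - 0.5) / n
    qq_theoretical = sps.norm.ppf(probs)
    if np.std(resid) < 1e-12:
        return ResidualDiagnostics(
            n=n, degenerate=True,
            normality_stat=float("nan"), normality_p=float("nan"),
            het_stat=float("nan"), het_p=float("nan"),
            qq_theoretical=qq_theoretical, qq_sample=order,
        )
    norm_stat, norm_p = sps.normaltest(resid)
    lm, lm_p, _, _ = het_breuschpagan(resid, fit.results.model.exog)
    return ResidualDiagnostics(
        n=n, degenerate=False,
        normality_stat=float(norm_stat), normality_p=float(norm_p),
        het_stat=float(lm), het_p=float(lm_p),
        qq_theoretical=qq_theoretical, qq_sample=order,
    )
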