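"""National impact of early labour-force exit: lost income, welfare, tax, GDP.

For every person out of the labour force because of diabetes, a
counterfactual asks what their annual income, welfare and tax would be if
they instead had the employment structure of the no-chronic-condition
population: a mixture over full-time, part-time and non-employed states with
that population's shares. Employed-state outcomes come from the fitted
log-linear models' covariate-adjusted median-scale predictions exp(x beta)
(a group-mean alternative is available behind a flag); the non-employed state
keeps the person's actual values. Per-record losses are weighted up to
national totals in AU$ million per year.

GDP loss uses the labour-productivity decomposition
GDP = GDP/H x H/EMP x EMP/LF x LF/Pop15+ x Pop15+: removing n workers while
holding productivity (GDP/H) and average hours (H/EMP) fixed costs
GDP/H x H/EMP x n, the marginal form of the identity. The sensitivity
scenario scales everything by the preventable fraction — the share of
diabetes at these ages that is Type 2 and hence potentially preventable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import FT_NO_CONDITION, NO_CONDITION_GROUPS, PT_NO_CONDITION
from .model import LogLinearFit, weighted_mean

__all__ = [
    "CounterfactualSpec",
    "GDPParameters",
    "NationalImpact",
    "counterfactual_economics",
    "reference_state_means",
    "national_losses",
    "gdp_loss",
    "gdp_loss_difference_form",
    "apply_preventable_fraction",
]

OUTCOMES = ("income", "welfare", "tax")


@dataclasses.dataclass
class CounterfactualSpec:
    """Employment structure assumed for the counterfactual population."""

    ft_share: float
    pt_share: float
    nonemployed_share: float

    def validate(self) -> None:
        shares = (self.ft_share, self.pt_share, self.nonemployed_share)
        if any(not 0 <= s <= 1 for s in shares):
            raise ValueError(f"shares must lie in [0, 1], got {shares}")
        if abs(sum(shares) - 1.0) > 1e-6:
            raise ValueError(f"shares must sum to 1, got {sum(shares):.6f}")

    @classmethod
    def from_survey(cls, survey: pd.DataFrame, weight_col: str = "weight") -> "CounterfactualSpec":
        """Weighted FT/PT/non-employed shares of the no-condition population."""
        ref = survey[survey["group"].isin(NO_CONDITION_GROUPS)]
        if ref.empty:
            raise ValueError("no no-condition records to derive employment shares from")
        total = ref[weight_col].sum()
        ft = ref.loc[ref["group"] == FT_NO_CONDITION, weight_col].sum()
        pt = ref.loc[ref["group"] == PT_NO_CONDITION, weight_col].sum()
        spec = cls(
            ft_share=float(ft / total),
            pt_share=float(pt / total),
            nonemployed_share=float((total - ft - pt) / total),
        )
        spec.validate()
        return spec


@dataclasses.dataclass
class GDPParameters:
    """Levels and rates of the GDP decomposition (2010-era values).

    gdp_per_hour (AU$/hour) and hours_per_worker (hours/year/worker) set the
    output value of one worker; employment rate, participation rate and the
    15+ population close the identity so the implied total GDP can be
    sanity-checked. Defaults are illustrative round figures for Australia in
    2010 (implied GDP ~= AU$1.33 trillion) — an assumption, since the source
    levels are not published alongside the loss estimates.
    """

    gdp_per_hour: float = 71.0
    hours_per_worker: float = 1_700.0
    employment_rate: float = 0.943
    participation_rate: float = 0.655
    population_15plus: float = 17_800_000.0

    def validate(self) -> None:
        for field in ("gdp_per_hour", "hours_per_worker", "population_15plus"):
            if not getattr(self, field) > 0:
                raise ValueError(f"{field} must be strictly positive")
        for field in ("employment_rate", "participation_rate"):
            if not 0 < getattr(self, field) <= 1:
                raise ValueError(f"{field} must lie in (0, 1]")

    def gdp_total(self) -> float:
        """Total GDP implied by the identity, in AU$."""
        return (
            self.gdp_per_hour
            * self.hours_per_worker
            * self.employment_rate
            * self.participation_rate
            * self.population_15plus
        )


@dataclasses.dataclass
class NationalImpact:
    """Weighted national totals for one scenario (AU$ million per year)."""

    n_out_of_lf: float
    lost_income: float
    extra_welfare: float
    lost_tax: float
    gdp_loss: float
    scenario: str = "base"

    def rounded(self) -> "NationalImpact":
        """Reporting precision: persons to integers, money to 0.1 AU$M."""
        return NationalImpact(
            n_out_of_lf=round(self.n_out_of_lf),
            lost_income=round(self.lost_income, 1),
            extra_welfare=round(self.extra_welfare, 1),
            lost_tax=round(self.lost_tax, 1),
            gdp_loss=round(self.gdp_loss, 1) if not math.isnan(self.gdp_loss) else self.gdp_loss,
            scenario=self.scenario,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def reference_state_means(
    matched: pd.DataFrame, weight_col: str = "weight"
) -> dict[str, dict[str, float]]:
    """Weighted mean income/welfare/tax of the FT and PT reference groups."""
    out: dict[str, dict[str, float]] = {}
    for state, group in (("ft", FT_NO_CONDITION), ("pt", PT_NO_CONDITION)):
        sub = matched[matched["group"] == group]
        if sub.empty:
            raise ValueError(f"reference group {group!r} absent from matched data")
        out[state] = {
            o: weighted_mean(sub[o], sub[weight_col]) for o in OUTCOMES
        }
    return out


def counterfactual_economics(
    nilf_records: pd.DataFrame,
    fits: Mapping[str, LogLinearFit],
    spec: CounterfactualSpec,
    method: str = "regression",
    reference_means: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-record counterfactual economics and losses for the NILF group.

    For each record, the counterfactual value of each outcome is the
    share-weighted mixture over the full-time and part-time employed states
    (predicted for that record's age/sex/education in the reference group)
    and the non-employed state (the record's actual value). Losses:
    income and tax losses are (counterfactual - actual) floored at zero;
    the welfare difference is sign-flipped into ``extra_welfare``.

    ``method="regression"`` (default) predicts employed-state outcomes with
    the fitted log-linear models; ``method="group_mean"`` uses the weighted
    reference-group means in ``reference_means`` (see
    :func:`reference_state_means`), ignoring the record's covariates.
    """
    spec.validate()
    if method not in ("regression", "group_mean"):
        raise ValueError(f"unknown counterfactual method {method!r}")
    out = nilf_records.copy()
    predictions: dict[str, dict[str, np.ndarray]] = {"ft": {}, "pt": {}}
    if method == "regression":
        missing = [o for o in OUTCOMES if o not in fits]
        if missing:
            raise ValueError(f"missing fitted model(s) for outcome(s) {missing}")
        for state, group in (("ft", FT_NO_CONDITION), ("pt", PT_NO_CONDITION)):
            counter = nilf_records.copy()
            counter["group"] = group
            for o in OUTCOMES:
                fit = fits[o]
                if group not in fit.levels["group"]:
                    raise ValueError(f"reference group {group!r} absent from {o} model")
                predictions[state][o] = np.clip(fit.predict_median(counter), 0.0, None)
    else:
        if reference_means is None:
            raise ValueError("method='group_mean' requires reference_means")
        n = len(nilf_records)
        for state in ("ft", "pt"):
            for o in OUTCOMES:
                predictions[state][o] = np.full(n, float(reference_means[state][o]))

    for o in OUTCOMES:
        actual = nilf_records[o].to_numpy(float)
        cf = (
            spec.ft_share * predictions["ft"][o]
            + spec.pt_share * predictions["pt"][o]
            + spec.nonemployed_share * actual
        )
        out[f"cf_{o}"] = cf
    out["income_loss"] = np.clip(out["cf_income"] - out["income"], 0.0, None)
    out["tax_loss"] = np.clip(out["cf_tax"] - out["tax"], 0.0, None)
    out["extra_welfare"] = out["welfare"] - out["cf_welfare"]
    return out


def national_losses(
    losses: pd.DataFrame,
    weights: Sequence[float] | pd.Series,
    gdp_params: GDPParameters | None = None,
    scenario: str = "base",
) -> NationalImpact:
    """Weight per-record losses up to national totals (AU$ million/year).

    Each monetary figure is sum_i w_i * loss_i / 1e6; the worker count
    n = sum_i w_i also drives the GDP loss when ``gdp_params`` is given
    (otherwise GDP loss is NaN). No rounding is applied here — use
    :meth:`NationalImpact.rounded` at reporting time.
    """
    w = np.asarray(weights, float)
    if len(w) != len(losses):
        raise ValueError(f"{len(w)} weights for {len(losses)} loss records")
    n = float(w.sum()) if len(w) else 0.0
    def total(col: str) -> float:
        if not len(w):
            return 0.0
        return float(np.sum(w * losses[col].to_numpy(float)) / 1e6)

    gdp = gdp_loss(n, gdp_params) if gdp_params is not None else float("nan")
    return NationalImpact(
        n_out_of_lf=n,
        lost_income=total("income_loss"),
        extra_welfare=total("extra_welfare"),
        lost_tax=total("tax_loss"),
        gdp_loss=gdp,
        scenario=scenario,
    )


def gdp_loss(n_workers_removed: float, params: GDPParameters) -> float:
    """GDP forgone by removing workers, AU$ million/year (marginal form).

    Holding productivity and average hours fixed, each lost worker costs
    gdp_per_hour * hours_per_worker; the second-order participation-rate
    feedback in the full identity is dropped (it is exactly zero when the
    worker leaves both employment and the labour force, see
    :func:`gdp_loss_difference_form`).
    """
    if n_workers_removed < 0:
        raise ValueError("worker count must be non-negative")
    params.validate()
    return params.gdp_per_hour * params.hours_per_worker * n_workers_removed / 1e6


def gdp_loss_difference_form(n_workers_removed: float, params: GDPParameters) -> float:
    """GDP loss as a before/after difference of the full identity (AU$M).

    Both employment and the labour force shrink by the removed workers while
    GDP/H and H/EMP stay fixed; the implied employment and participation
    rates adjust. Algebraically identical to the marginal form — provided as
    an independent route for verification.
    """
    if n_workers_removed < 0:
        raise ValueError("worker count must be non-negative")
    params.validate()
    lf = params.participation_rate * params.population_15plus
    emp = params.employment_rate * lf
    n = n_workers_removed
    if n > emp:
        raise ValueError("cannot remove more workers than are employed")
    lf_after, emp_after = lf - n, emp - n
    before = params.gdp_per_hour * params.hours_per_worker * emp
    after = (
        params.gdp_per_hour
        * params.hours_per_worker
        * (emp_after / lf_after if lf_after > 0 else 0.0)
        * (lf_after / params.population_15plus)
        * params.population_15plus
    )
    return (before - after) / 1e6


def apply_preventable_fraction(base: NationalImpact, fraction: float) -> NationalImpact:
    """Scale a base scenario by the preventable fraction (Type 2 share).

    Persons are rounded to the nearest integer and money to 0.1 AU$ million,
    the reporting precision of the scenario table.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"preventable fraction must lie in [0, 1], got {fraction}")
    scaled = NationalImpact(
        n_out_of_lf=base.n_out_of_lf * fraction,
        lost_income=base.lost_income * fraction,
        extra_welfare=base.extra_welfare * fraction,
        lost_tax=base.lost_tax * fraction,
        gdp_loss=base.gdp_loss * fraction,
        scenario="preventable",
    )
    return scaled.rounded()
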