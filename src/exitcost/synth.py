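"""Seeded synthetic survey, donor and benchmark generation.

The confidential unit-record sources behind the analysis (a national
disability survey for the base population, a dynamic microsimulation snapshot
for detailed economics) cannot be shipped, so this module generates microdata
with the statistical structure the downstream stages assume:

* seven labour-force/chronic-condition groups with fixed sampled and weighted
  sizes;
* annual income that is log-normal within group, with a shared log-linear
  mean structure (group contrast + age/sex/education effects) so that the
  regression stage estimates a well-defined truth;
* welfare payments that are zero-inflated log-normal (employed groups have
  median 0 with small positive means);
* tax computed deterministically from income through a piecewise-linear
  marginal schedule;
* donor records carrying only the ten matching variables plus exact
  economics, emulating a model snapshot that has no condition information.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .calibrate import BenchmarkTable
from .categories import (
    GROUP_TO_LF_STATUS,
    GROUPS,
    HOURS_NONE,
    LF_FULL_TIME,
    LF_PART_TIME,
    MATCH_VARIABLES,
    STRATUM_VARIABLES,
)

__all__ = [
    "PopulationSpec",
    "SpecValidationError",
    "default_spec",
    "scaled_spec",
    "generate_survey",
    "generate_donors",
    "generate_benchmarks",
    "apply_tax_schedule",
    "lognormal_sigma_from_mean_median",
    "zero_inflated_lognormal_params",
]


class SpecValidationError(ValueError):
    """A population spec violates an invariant; the message names the field."""


def lognormal_sigma_from_mean_median(mean: float, median: float) -> float:
    """Log-scale sigma of a log-normal with the given mean and median.

    mean/median = exp(sigma^2 / 2), hence sigma = sqrt(2 ln(mean/median)).
    Requires mean > median > 0 (right skew).
    """
    if not (mean > median > 0):
        raise ValueError("need mean > median > 0 for a log-normal fit")
    return math.sqrt(2.0 * math.log(mean / median))


def zero_inflated_lognormal_params(
    p_positive: float, mean: float, median: float | None = None, sigma: float = 1.0
) -> tuple[float, float]:
    """Log-normal (meanlog, sdlog) for the positive part of a zero-inflated mix.

    The mixture puts mass ``1 - p_positive`` at zero. The positive part is
    chosen so the mixture mean equals ``mean``; if ``median`` is given (and the
    mixture median is positive, i.e. p_positive > 0.5) sdlog is solved so the
    mixture median equals it, otherwise ``sigma`` is used as sdlog.
    """
    if not 0 < p_positive <= 1:
        raise ValueError("p_positive must be in (0, 1]")
    log_pos_mean = math.log(mean / p_positive)
    if median is None:
        return log_pos_mean - sigma**2 / 2.0, sigma
    if p_positive <= 0.5:
        raise ValueError("a positive mixture median requires p_positive > 0.5")
    # F_pos(median) = (p - 1/2) / p; meanlog = log(median) - z * sdlog with
    # z the corresponding normal quantile, and meanlog + sdlog^2/2 must equal
    # log(mean / p). Quadratic in sdlog.
    from scipy.stats import norm

    z = norm.ppf((p_positive - 0.5) / p_positive)
    delta = log_pos_mean - math.log(median)
    disc = z**2 + 2.0 * delta
    if disc <= 0:
        raise ValueError("mean/median anchors inconsistent with p_positive")
    sdlog = float(z + math.sqrt(disc))
    if sdlog <= 0:
        raise ValueError("mean/median anchors imply non-positive sdlog")
    return float(math.log(median) - z * sdlog), sdlog


def apply_tax_schedule(
    income: np.ndarray | float, schedule: Sequence[tuple[float, float]]
) -> np.ndarray | float:
    """Annual tax under a piecewise-linear marginal schedule.

    ``schedule`` is a sequence of (lower threshold, marginal rate) pairs with
    increasing thresholds; the rate applies to income above its threshold up
    to the next one.
    """
    y = np.asarray(income, dtype=float)
    tax = np.zeros_like(y)
    thresholds = [t for t, _ in schedule] + [math.inf]
    for (lo, rate), hi in zip(schedule, thresholds[1:]):
        tax += rate * np.clip(y - lo, 0.0, hi - lo)
    return tax if isinstance(income, np.ndarray) else float(tax)


@dataclasses.dataclass
class PopulationSpec:
    """Full parameterisation of the synthetic population.

    Income model: log(income) = base_log_income + income_effects[group]
    + sum of covariate_effects over the record's age/sex/education,
    + income_sigmas[group] * standard normal noise.
    """

    group_sizes: dict[str, float]
    sample_sizes: dict[str, int]
    base_log_income: float
    income_effects: dict[str, float]
    income_sigmas: dict[str, float]
    covariate_effects: dict[str, dict[str, float]]
    welfare_params: dict[str, dict[str, float]]  # p_positive, meanlog, sdlog
    tax_schedule: tuple[tuple[float, float], ...]
    covariate_mixes: dict[str, dict[str, dict]]
    quintile_edges: tuple[float, ...] = defaults.QUINTILE_EDGES
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for g, v in self.group_sizes.items():
            if not v > 0:
                raise SpecValidationError(f"group_sizes[{g!r}] must be > 0, got {v}")
        for g, v in self.sample_sizes.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise SpecValidationError(f"sample_sizes[{g!r}] must be a positive integer, got {v}")
            if g not in self.group_sizes:
                raise SpecValidationError(f"sample_sizes[{g!r}] has no matching group_sizes entry")
        for g, s in self.income_sigmas.items():
            if not s > 0:
                raise SpecValidationError(f"income_sigmas[{g!r}] must be > 0, got {s}")
        prev_t, prev_r = -math.inf, -math.inf
        for t, r in self.tax_schedule:
            if t <= prev_t:
                raise SpecValidationError("tax_schedule thresholds must be strictly increasing")
            if r < prev_r or not 0 <= r < 1:
                raise SpecValidationError("tax_schedule rates must be non-decreasing and in [0, 1)")
            prev_t, prev_r = t, r
        for g, p in self.welfare_params.items():
            if not 0 <= p["p_positive"] <= 1:
                raise SpecValidationError(f"welfare_params[{g!r}].p_positive must be in [0, 1]")
            if p["p_positive"] > 0 and not p["sdlog"] > 0:
                raise SpecValidationError(f"welfare_params[{g!r}].sdlog must be > 0")
        for g, mix in self.covariate_mixes.items():
            for var, dist in mix.items():
                total = sum(dist.values())
                if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-6:
                    raise SpecValidationError(
                        f"covariate_mixes[{g!r}][{var!r}] must be a probability "
                        f"distribution summing to 1 (sums to {total})"
                    )
        if list(self.quintile_edges) != sorted(self.quintile_edges):
            raise SpecValidationError("quintile_edges must be increasing")

    # -- derived quantities -------------------------------------------------

    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUPS if g in self.sample_sizes)

    def mean_covariate_effect(self, group: str) -> float:
        """Expected covariate contribution to log income for a group's mix."""
        total = 0.0
        for var, effects in self.covariate_effects.items():
            dist = self.covariate_mixes[group][var]
            total += sum(p * effects[cat] for cat, p in dist.items())
        return total

    def target_median_income(self, group: str) -> float:
        """Median annual income implied by the spec for a group (AU$/yr)."""
        return math.exp(
            self.base_log_income
            + self.income_effects[group]
            + self.mean_covariate_effect(group)
        )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tax_schedule"] = [list(x) for x in self.tax_schedule]
        d["quintile_edges"] = list(self.quintile_edges)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        d = dict(d)
        d["tax_schedule"] = tuple((float(t), float(r)) for t, r in d["tax_schedule"])
        d["quintile_edges"] = tuple(float(e) for e in d["quintile_edges"])
        d["sample_sizes"] = {g: int(n) for g, n in d["sample_sizes"].items()}
        spec = cls(**d)
        spec.validate()
        return spec


def default_spec(seed: int = 0) -> PopulationSpec:
    """The default study conditions (see :mod:`exitcost.defaults`)."""
    mixes = defaults.covariate_mixes()
    sigmas = {
        g: lognormal_sigma_from_mean_median(mean, median)
        for g, (mean, median) in defaults.INCOME_ANCHORS.items()
    }
    welfare = {}
    for g, anchor in defaults.WELFARE_ANCHORS.items():
        meanlog, sdlog = zero_inflated_lognormal_params(
            anchor["p_positive"], anchor["mean"], anchor["median"]
        )
        welfare[g] = {"p_positive": anchor["p_positive"], "meanlog": meanlog, "sdlog": sdlog}
    spec = PopulationSpec(
        group_sizes=dict(defaults.GROUP_SIZES),
        sample_sizes=dict(defaults.SAMPLE_SIZES),
        base_log_income=0.0,  # anchored below
        income_effects=dict(defaults.INCOME_EFFECTS),
        income_sigmas=sigmas,
        covariate_effects={v: dict(e) for v, e in defaults.COVARIATE_EFFECTS.items()},
        welfare_params=welfare,
        tax_schedule=tuple(defaults.TAX_SCHEDULE),
        covariate_mixes=mixes,
        quintile_edges=tuple(defaults.QUINTILE_EDGES),
        seed=seed,
    )
    # Anchor the reference group's median income to the published $54,795.
    ref = "ft_no_condition"
    _, ref_median = defaults.INCOME_ANCHORS[ref]
    spec.base_log_income = math.log(ref_median) - spec.mean_covariate_effect(ref)
    spec.validate()
    return spec


def scaled_spec(n_total: int, seed: int = 0) -> PopulationSpec:
    """Default spec with sample sizes rescaled to ``n_total`` records.

    Group proportions follow the default sample, rounded by largest remainder
    so counts sum exactly to ``n_total`` (every group keeps at least one
    record). Weighted group sizes are scaled with the same factor so design
    weights are unchanged.
    """
    if n_total < len(GROUPS):
        raise ValueError(f"n_total must be at least {len(GROUPS)}")
    spec = default_spec(seed=seed)
    base = spec.sample_sizes
    total = sum(base.values())
    raw = {g: n_total * n / total for g, n in base.items()}
    counts = {g: max(1, int(math.floor(r))) for g, r in raw.items()}
    remainders = sorted(raw, key=lambda g: raw[g] - math.floor(raw[g]), reverse=True)
    i = 0
    while sum(counts.values()) < n_total:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    while sum(counts.values()) > n_total:
        g = max(counts, key=counts.get)
        counts[g] -= 1
    factor = n_total / total
    spec.sample_sizes = counts
    spec.group_sizes = {g: v * factor for g, v in spec.group_sizes.items()}
    spec.validate()
    return spec


# -- record generation ------------------------------------------------------


def _draw_categorical(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    cats = list(dist.keys())
    probs = np.asarray([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.asarray(cats, dtype=object)[idx]

def _draw_group(spec: PopulationSpec, group: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates plus exact economics for ``n`` records of one group."""
    mix = spec.covariate_mixes[group]
    cols: dict[str, np.ndarray] = {}
    for var in ("age_group", "sex", "education", "income_unit", "hours_band",
                "age_pension", "dsp", "home_owner", "n_conditions"):
        cols[var] = _draw_categorical(rng, mix[var], n)
    linpred = np.full(n, spec.base_log_income + spec.income_effects[group])
    for var, effects in spec.covariate_effects.items():
        linpred += np.asarray([effects[c] for c in cols[var]])
    income = np.exp(linpred + spec.income_sigmas[group] * rng.standard_normal(n))
    wp = spec.welfare_params[group]
    positive = rng.random(n) < wp["p_positive"]
    welfare = np.where(
        positive, np.exp(wp["meanlog"] + wp["sdlog"] * rng.standard_normal(n)), 0.0
    )
    tax = apply_tax_schedule(income, spec.tax_schedule)
    df = pd.DataFrame(cols)
    df.insert(0, "group", group)
    df.insert(1, "lf_status", GROUP_TO_LF_STATUS[group])
    df["income_quintile"] = np.searchsorted(np.asarray(spec.quintile_edges), income) + 1
    df["income"] = income
    df["welfare"] = welfare
    df["tax"] = tax
    for flag in ("age_pension", "dsp", "home_owner", "n_conditions"):
        df[flag] = df[flag].astype(int)
    return df


def generate_survey(
    spec: PopulationSpec,
    seed: int | None = None,
    include_economics: bool = False,
) -> pd.DataFrame:
    """Generate the survey base population.

    One row per person with the ten matching variables, chronic-condition
    count, group label and a positive design weight whose group totals
    approximate the spec's weighted group sizes (each group's weights carry
    ±15% multiplicative jitter around size/sample so that calibration has
    real work to do). Incomes are drawn internally to band the income
    quintile; pass ``include_economics=True`` to keep the exact income,
    welfare and tax columns (useful for parameter-recovery studies — the
    production pipeline imputes economics by matching instead).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for group in spec.groups():
        n = spec.sample_sizes[group]
        df = _draw_group(spec, group, n, rng)
        base_weight = spec.group_sizes[group] / n
        df["design_weight"] = base_weight * rng.uniform(0.85, 1.15, size=n)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "record_id", [f"s{i:06d}" for i in range(len(out))])
    if not include_economics:
        out = out.drop(columns=["income", "welfare", "tax"])
    return out


def generate_donors(spec: PopulationSpec, n: int, seed: int | None = None) -> pd.DataFrame:
    """Generate the donor pool carrying exact economics.

    Donors are drawn from the same population model as the survey (group
    mixture proportional to weighted group sizes) but, like a model snapshot
    with no health module, carry only the ten matching variables plus exact
    annual income, welfare and tax.
    """
    if n <= 0:
        raise ValueError(f"donor count must be positive, got {n}")
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups = spec.groups()
    sizes = np.asarray([spec.group_sizes[g] for g in groups], dtype=float)
    draws = rng.choice(len(groups), size=n, p=sizes / sizes.sum())
    frames = []
    for i, group in enumerate(groups):
        k = int((draws == i).sum())
        if k:
            frames.append(_draw_group(spec, group, k, rng))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "donor_id", [f"d{i:06d}" for i in range(len(out))])
    return out[["donor_id", *MATCH_VARIABLES, "income", "welfare", "tax"]]


# -- benchmarks -------------------------------------------------------------


def _category_probability(spec: PopulationSpec, group: str, var: str, cat) -> float:
    if var == "lf_status":
        return 1.0 if GROUP_TO_LF_STATUS[group] == cat else 0.0
    return spec.covariate_mixes[group][var].get(cat, 0.0)


def _categories(spec: PopulationSpec, var: str) -> list:
    if var == "lf_status":
        return sorted({GROUP_TO_LF_STATUS[g] for g in spec.groups()})
    cats: list = []
    for g in spec.groups():
        for c in spec.covariate_mixes[g][var]:
            if c not in cats:
                cats.append(c)
    return cats


def generate_benchmarks(spec: PopulationSpec, strata: Sequence[str]) -> BenchmarkTable:
    """Expected population totals over the cross-classification of ``strata``.

    Cell totals are the spec's weighted group sizes distributed over the
    stratum cells using the generator's covariate mixes (covariates are
    independent within group), so they are the population margins the
    generator itself implies. Cells with zero expected count are dropped.
    """
    import itertools

    spec.validate()
    unknown = [v for v in strata if v not in STRATUM_VARIABLES]
    if unknown:
        raise ValueError(f"unknown stratum variable(s): {unknown}; choose from {STRATUM_VARIABLES}")
    cells = []
    category_sets = [_categories(spec, v) for v in strata]
    for combo in itertools.product(*category_sets):
        total = 0.0
        for g in spec.groups():
            p = 1.0
            for var, cat in zip(strata, combo):
                p *= _category_probability(spec, g, var, cat)
            total += spec.group_sizes[g] * p
        if total > 0:
            cells.append((dict(zip(strata, combo)), total))
    return BenchmarkTable(cells=cells, total_population=sum(spec.group_sizes.values()))
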