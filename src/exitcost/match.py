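"""Synthetic matching: impute exact economics from donors onto survey records.

Each survey record is paired with a donor record that agrees on ten
categorical matching variables (labour force status, income unit type, income
quintile, age-pension and disability-support-pension receipt, sex, age group,
hours band, education, home ownership) and receives that donor's exact annual
income, welfare payments and tax liability.

When a recipient's full ten-variable cell contains no donor, variables are
relaxed one at a time from the end of a configurable priority list (default:
the conventional listing order, strongest income predictors first, so labour
force status — the analysis axis — is never dropped). Ties among eligible
donors are broken uniformly at random under a caller-supplied seed, and donors
are reused with replacement, so the donor pool need not exceed the recipient
count.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import (
    HOURS_NONE,
    LF_FULL_TIME,
    LF_PART_TIME,
    MATCH_CATEGORIES,
    MATCH_VARIABLES,
)

__all__ = ["MatchKey", "MatchReport", "MatchingError", "build_match_key", "impute_economics"]

#: Default relaxation priority: variables dropped from the end of this tuple.
DEFAULT_PRIORITY = MATCH_VARIABLES

ECONOMIC_VARIABLES = ("income", "welfare", "tax")

MatchKey = tuple


class MatchingError(RuntimeError):
    """A recipient could not be matched even on the highest-priority variable."""


def build_match_key(record: Mapping, priority: Sequence[str] = DEFAULT_PRIORITY) -> MatchKey:
    """Ordered tuple of the ten matching variables for one record.

    Validates every component against its category set; non-employed records
    (labour force status unemployed/NILF) must carry the ``"none"`` hours
    sentinel, employed ones a real hours band. Raises ``ValueError`` naming
    the offending variable.
    """
    _validate_priority(priority)
    values = []
    for var in priority:
        if var not in record or pd.isna(record[var]):
            raise ValueError(f"record is missing matching variable {var!r}")
        value = record[var]
        allowed = MATCH_CATEGORIES[var]
        if var == "hours_band":
            employed = record.get("lf_status") in (LF_FULL_TIME, LF_PART_TIME)
            allowed = allowed if employed else (HOURS_NONE,)
        if value not in allowed:
            raise ValueError(f"invalid category {value!r} for matching variable {var!r}")
        values.append(value)
    return tuple(values)


def _validate_priority(priority: Sequence[str]) -> None:
    if sorted(priority) != sorted(MATCH_VARIABLES):
        raise ValueError(
            f"priority must be a permutation of the ten matching variables, got {list(priority)}"
        )


@dataclasses.dataclass
class MatchReport:
    """Per-record match provenance and aggregate quality measures."""

    per_record: pd.DataFrame  # record_id, donor_id, n_relaxed, pool_size
    exact_match_rate: float  # share of recipients matched on all ten variables
    relaxation_histogram: dict[int, int]  # n_relaxed -> count

    def to_dict(self) -> dict:
        return {
            "exact_match_rate": self.exact_match_rate,
            "relaxation_histogram": {int(k): int(v) for k, v in self.relaxation_histogram.items()},
            "n_matched": int(len(self.per_record)),
        }


def impute_economics(
    survey: pd.DataFrame,
    donors: pd.DataFrame,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    seed: int = 0,
) -> tuple[pd.DataFrame, MatchReport]:
    """Attach donor income, welfare and tax to every survey record.

    Returns the survey frame augmented with the three economic variables plus
    ``donor_id``, ``n_relaxed`` (variables dropped to find a non-empty pool)
    and ``pool_size``, together with a :class:`MatchReport`. Reproducible for
    identical inputs and ``seed``.
    """
    if len(donors) == 0:
        raise ValueError("donor set is empty")
    _validate_priority(priority)
    priority = list(priority)
    rng = np.random.default_rng(seed)

    donor_keys = [build_match_key(row, priority) for row in donors.to_dict("records")]
    survey_keys = [build_match_key(row, priority) for row in survey.to_dict("records")]

    # Donor index pools at each relaxation level: level r keys on the first
    # (10 - r) priority variables. Built lazily — most recipients match early.
    pools: dict[int, dict[tuple, list[int]]] = {}

    def pool_at(level: int) -> dict[tuple, list[int]]:
        if level not in pools:
            index: dict[tuple, list[int]] = {}
            cut = len(priority) - level
            for i, key in enumerate(donor_keys):
                index.setdefault(key[:cut], []).append(i)
            pools[level] = index
        return pools[level]

    donor_ids = donors["donor_id"].to_numpy() if "donor_id" in donors.columns else donors.index.to_numpy()
    econ = donors[list(ECONOMIC_VARIABLES)].to_numpy(dtype=float)

    chosen = np.empty(len(survey), dtype=int)
    relaxed = np.empty(len(survey), dtype=int)
    pool_sizes = np.empty(len(survey), dtype=int)
    for i, key in enumerate(survey_keys):
        for level in range(len(priority)):
            candidates = pool_at(level).get(key[: len(priority) - level])
            if candidates:
                chosen[i] = candidates[rng.integers(len(candidates))]
                relaxed[i] = level
                pool_sizes[i] = len(candidates)
                break
        else:
            raise MatchingError(
                f"record {survey.index[i]!r} unmatched even on {priority[0]!r} alone "
                f"(value {key[0]!r} absent from donors)"
            )

    augmented = survey.copy()
    for j, var in enumerate(ECONOMIC_VARIABLES):
        augmented[var] = econ[chosen, j]
    augmented["donor_id"] = donor_ids[chosen]
    augmented["n_relaxed"] = relaxed
    augmented["pool_size"] = pool_sizes

    record_ids = (
        survey["record_id"].to_numpy() if "record_id" in survey.columns else survey.index.to_numpy()
    )
    per_record = pd.DataFrame(
        {
            "record_id": record_ids,
            "donor_id": donor_ids[chosen],
            "n_relaxed": relaxed,
            "pool_size": pool_sizes,
        }
    )
    hist = {int(k): int(v) for k, v in zip(*np.unique(relaxed, return_counts=True))}
    report = MatchReport(
        per_record=per_record,
        exact_match_rate=float(np.mean(relaxed == 0)),
        relaxation_histogram=hist,
    )
    return augmented, report
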