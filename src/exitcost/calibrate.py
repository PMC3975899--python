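"""Generalized-regression (GREG) survey weight calibration with bounds.

Given survey records with design weights ``d`` and a table of population
benchmark totals ``T`` over categorical cells, find calibrated weights ``w``
minimising the chi-squared distance

    sum_i (w_i - d_i)^2 / (2 d_i)

subject to the benchmark equations ``X' w = T`` (``X`` the cell-membership
indicator matrix) and box constraints ``L d_i <= w_i <= U d_i``. The
unbounded problem has the closed-form GREG solution

    w = d + D X (X' D X)^+ (T - X' d),      D = diag(d);

bounds are handled by the truncate-and-resolve scheme used by production
reweighting software: weights pushed outside their box are fixed at the bound
and the regression is re-solved on the remaining records against the residual
targets, iterating until no new weight violates its bounds.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkTable",
    "CalibrationResult",
    "CalibrationError",
    "calibrate_weights",
    "check_benchmarks",
]


class CalibrationError(ValueError):
    """Calibration cannot proceed (e.g. a benchmark cell with no records)."""


@dataclasses.dataclass
class BenchmarkTable:
    """Population totals by stratum cell.

    ``cells`` is a list of ``(descriptor, target)`` pairs where the descriptor
    maps stratum variables to categories (a record belongs to the cell when it
    matches every entry) and the target is the population count in persons.
    """

    cells: list[tuple[dict, float]]
    total_population: float

    def validate(self) -> None:
        for desc, target in self.cells:
            if not target > 0:
                raise CalibrationError(f"benchmark cell {desc} has non-positive target {target}")

    def membership_matrix(self, records: pd.DataFrame) -> np.ndarray:
        """Boolean (n_records, n_cells) cell-membership indicators."""
        n = len(records)
        x = np.zeros((n, len(self.cells)), dtype=float)
        for j, (desc, _) in enumerate(self.cells):
            mask = np.ones(n, dtype=bool)
            for var, cat in desc.items():
                if var not in records.columns:
                    raise CalibrationError(f"records lack stratum variable {var!r}")
                mask &= (records[var] == cat).to_numpy()
            x[:, j] = mask
        return x

    def targets(self) -> np.ndarray:
        return np.asarray([t for _, t in self.cells], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [{**desc, "target": t} for desc, t in self.cells]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, target_col: str = "target") -> "BenchmarkTable":
        strata = [c for c in df.columns if c != target_col]
        cells = [
            (row[strata].to_dict(), float(row[target_col])) for _, row in df.iterrows()
        ]
        return cls(cells=cells, total_population=float(df[target_col].sum()))


@dataclasses.dataclass
class CalibrationResult:
    weights: pd.Series  # persons/record, aligned with the input records
    iterations: int
    max_constraint_violation: float  # max relative benchmark error
    truncated_count: int  # records whose weight sits on a bound
    converged: bool


def _greg_solve(d: np.ndarray, x: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Unbounded GREG adjustment: w = d + D x lambda with (x'Dx) lambda = resid.

    ``lstsq`` handles the rank deficiency that arises when margins overlap
    (e.g. two margins each summing to the grand total).
    """
    xtdx = x.T @ (d[:, None] * x)
    lam, *_ = np.linalg.lstsq(xtdx, resid, rcond=None)
    return d * (1.0 + x @ lam)


def calibrate_weights(
    records: pd.DataFrame,
    benchmarks: BenchmarkTable,
    bounds: tuple[float, float] = (0.3, 3.0),
    tol: float = 1e-6,
    max_iter: int = 50,
    weight_col: str = "design_weight",
) -> CalibrationResult:
    """Calibrate design weights to benchmark totals.

    Parameters follow common production settings: adjustment bounds
    ``(L, U)`` multiply each design weight, ``tol`` is the maximum relative
    benchmark error accepted as converged. Records belonging to no benchmark
    cell keep their design weight (with a warning). Raises
    :class:`CalibrationError` when a benchmark cell contains no records. On
    non-convergence the result is returned flagged, with the violation
    reported.
    """
    lower, upper = bounds
    if not (0 < lower <= 1 <= upper):
        raise ValueError(f"bounds must satisfy 0 < L <= 1 <= U, got {bounds}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    benchmarks.validate()
    d = records[weight_col].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise CalibrationError("all design weights must be strictly positive")
    x = benchmarks.membership_matrix(records)
    targets = benchmarks.targets()

    empty = np.flatnonzero(x.sum(axis=0) == 0)
    if empty.size:
        descs = [benchmarks.cells[j][0] for j in empty]
        raise CalibrationError(f"benchmark cell(s) with no survey records: {descs}")

    uncovered = x.sum(axis=1) == 0
    if uncovered.any():
        msg = f"{int(uncovered.sum())} record(s) belong to no benchmark cell; weights pass through"
        warnings.warn(msg)
        logger.warning(msg)

    def max_rel_violation(w: np.ndarray) -> float:
        return float(np.max(np.abs(x.T @ w - targets) / targets))

    w = d.copy()
    if max_rel_violation(w) <= tol:
        return CalibrationResult(
            weights=pd.Series(w, index=records.index, name="weight"),
            iterations=1,
            max_constraint_violation=max_rel_violation(w),
            truncated_count=0,
            converged=True,
        )

    lo, hi = lower * d, upper * d
    fixed = uncovered.copy()  # uncovered records never move
    w[fixed] = d[fixed]
    for iteration in range(1, max_iter + 1):
        free = ~fixed
        if not free.any():
            break
        # Targets net of the mass contributed by bound-fixed records, less
        # the free records' design-weight contribution: the residual the
        # free-set regression must absorb.
        resid_free = targets - x[fixed].T @ w[fixed] - x[free].T @ d[free]
        w[free] = _greg_solve(d[free], x[free], resid_free)
        too_low = free & (w < lo - 1e-12 * d)
        too_high = free & (w > hi + 1e-12 * d)
        if not (too_low.any() or too_high.any()):
            break
        w[too_low] = lo[too_low]
        w[too_high] = hi[too_high]
        fixed |= too_low | too_high
    else:
        iteration = max_iter

    w = np.clip(w, lo, hi)
    w[uncovered] = d[uncovered]
    violation = max_rel_violation(w)
    on_bound = (np.abs(w - lo) <= 1e-9 * d) | (np.abs(w - hi) <= 1e-9 * d)
    converged = violation <= tol
    if not converged:
        logger.warning(
            "calibration did not converge: max relative violation %.3g after %d iteration(s)",
            violation, iteration,
        )
    return CalibrationResult(
        weights=pd.Series(w, index=records.index, name="weight"),
        iterations=iteration,
        max_constraint_violation=violation,
        truncated_count=int(on_bound.sum()),
        converged=converged,
    )


def check_benchmarks(
    records: pd.DataFrame,
    weights: Sequence[float] | pd.Series,
    benchmarks: BenchmarkTable,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-cell relative benchmark errors |sum(w x) - T| / T.

    Returns one row per cell with the achieved weighted total, target,
    relative error and an ``ok`` flag (error <= tol).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(records):
        raise ValueError(f"{len(w)} weights for {len(records)} records")
    x = benchmarks.membership_matrix(records)
    achieved = x.T @ w
    targets = benchmarks.targets()
    rel = np.abs(achieved - targets) / targets
    rows = []
    for (desc, target), a, r in zip(benchmarks.cells, achieved, rel):
        rows.append({"cell": desc, "target": target, "achieved": a, "rel_error": r, "ok": r <= tol})
    return pd.DataFrame(rows)
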