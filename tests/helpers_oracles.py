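"""Independent oracles shared by unit and acceptance tests.

These deliberately take different computational routes from the package:
the calibration oracle solves the generic equality-constrained quadratic
program through its KKT block system, and the matching oracle enumerates
donor pools by brute-force scanning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from exitcost.calibrate import BenchmarkTable


def qp_calibration_oracle(d: np.ndarray, x: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min sum (w-d)^2 / (2d) s.t. x' w = targets via the KKT system.

    Stationarity gives w/d + x lam = 1 (elementwise), so the block system
    [diag(1/d) x; x' 0] [w; lam] = [1; targets] characterises the optimum.
    Solved with lstsq to tolerate redundant (consistent) constraints.
    """
    n, k = x.shape
    top = np.hstack([np.diag(1.0 / d), x])
    bottom = np.hstack([x.T, np.zeros((k, k))])
    a = np.vstack([top, bottom])
    b = np.concatenate([np.ones(n), targets])
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:n]


def random_calibration_instance(rng: np.random.Generator):
    """A small feasible instance: records, two margins, consistent targets.

    Targets are the weighted totals of a random strictly positive weight
    vector, so the constraint system is always consistent and the optimum is
    interior for wide bounds.
    """
    n = int(rng.integers(6, 21))
    records = pd.DataFrame(
        {
            "a": rng.choice(["a1", "a2"], size=n),
            "b": rng.choice(["b1", "b2", "b3"], size=n),
            "design_weight": rng.uniform(0.5, 3.0, size=n),
        }
    )
    # ensure every cell of both margins is populated
    records.loc[0:1, "a"] = ["a1", "a2"]
    records.loc[0:2, "b"] = ["b1", "b2", "b3"]
    w_star = records["design_weight"].to_numpy() * rng.uniform(0.7, 1.4, size=n)
    cells = []
    for var, cats in (("a", ["a1", "a2"]), ("b", ["b1", "b2", "b3"])):
        for cat in cats:
            mask = (records[var] == cat).to_numpy()
            cells.append(({var: cat}, float(w_star[mask].sum())))
    table = BenchmarkTable(cells=cells, total_population=float(w_star.sum()))
    return records, table


def brute_force_match_pool(recipient: dict, donors: pd.DataFrame, priority) -> tuple[int, list]:
    """Smallest relaxation level with a non-empty donor pool, by full scan.

    Returns (n_relaxed, donor positional indices). Level r keeps the first
    len(priority) - r priority variables.
    """
    for level in range(len(priority)):
        keep = list(priority)[: len(priority) - level]
        pool = [
            i
            for i, row in enumerate(donors.to_dict("records"))
            if all(row[v] == recipient[v] for v in keep)
        ]
        if pool:
            return level, pool
    raise AssertionError("no pool at any level")
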