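"""Descriptives, log-linear regression, percent transform, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitcost import (
    diagnostics,
    fit_log_model,
    group_effects,
    percent_difference,
    summarize_by_group,
    weighted_mean,
    weighted_median,
    weighted_sd,
)
from exitcost.categories import REPORTED_GROUPS


class TestWeightedStatistics:
    def test_single_record_degenerate(self):
        assert weighted_mean([7.0], [3.0]) == 7.0
        assert weighted_median([7.0], [3.0]) == 7.0
        assert weighted_sd([7.0], [3.0]) == 0.0

    def test_hand_computed_example(self):
        values, weights = [10.0, 20.0, 30.0], [1.0, 1.0, 2.0]
        assert weighted_mean(values, weights) == pytest.approx(22.5)
        # median rule: smallest value whose cumulative weight reaches half the
        # total (cumulative 1, 2, 4 against half-total 2) -> 20, verified by
        # enumerating the rule directly below
        assert weighted_median(values, weights) == 20.0

    def test_median_rule_by_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(1, 12)
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 3.0, size=n)
            order = np.argsort(y)
            ys, cum = y[order], np.cumsum(w[order])
            enumerated = next(v for v, c in zip(ys, cum) if c >= 0.5 * cum[-1])
            assert weighted_median(y, w) == pytest.approx(enumerated)

    @given(
        value=st.floats(-1e6, 1e6),
        weights=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_weighted_mean_of_constant_is_constant(self, value, weights):
        values = [value] * len(weights)
        assert weighted_mean(values, weights) == pytest.approx(value, abs=1e-6)
        assert weighted_median(values, weights) == value

    def test_summary_carries_reported_group_order(self, matched_small):
        table = summarize_by_group(matched_small, weight_col="weight")
        assert tuple(table.index[:5]) == REPORTED_GROUPS
        assert (table["weighted_n"] > 0).all()
        for col in ("income", "welfare", "tax"):
            assert (table[f"{col}_sd"] >= 0).all()
            assert (table[f"{col}_median"] <= table[f"{col}_mean"] + 1e9).all()

    def test_empty_group_omitted_with_warning(self, matched_small):
        with pytest.warns(UserWarning, match="no records"):
            table = summarize_by_group(
                matched_small, weight_col="weight", groups=["ft_no_condition", "ghost_group"]
            )
        assert "ghost_group" not in table.index


def _toy_dataset(rng, n=400, effects=None):
    """Two-group dataset with known log-linear structure."""
    effects = effects or {}
    group = rng.choice(["ft_no_condition", "nilf_diabetes"], size=n, p=[0.8, 0.2])
    age = rng.choice(["45-49", "60-64"], size=n)
    sex = rng.choice(["male", "female"], size=n)
    edu = rng.choice(["non_university", "university"], size=n)
    log_y = (
        10.0
        + np.where(group == "nilf_diabetes", effects.get("group", 0.0), 0.0)
        + np.where(age == "60-64", -0.2, 0.0)
        + np.where(sex == "female", -0.25, 0.0)
        + np.where(edu == "university", 0.35, 0.0)
        + 0.5 * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {"group": group, "age_group": age, "sex": sex, "education": edu, "income": np.exp(log_y)}
    )


class TestLogLinearFit:
    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        data = _toy_dataset(rng, n=60, effects={"group": -1.0})
        fit = fit_log_model(data, "income")
        # independent route: explicit dummy design + least squares
        x = np.column_stack(
            [
                np.ones(len(data)),
                data["group"].eq("nilf_diabetes").to_numpy(float),
                data["age_group"].eq("60-64").to_numpy(float),
                data["sex"].eq("female").to_numpy(float),
                data["education"].eq("university").to_numpy(float),
            ]
        )
        beta, *_ = np.linalg.lstsq(x, np.log(data["income"]), rcond=None)
        np.testing.assert_allclose(np.asarray(fit.results.params), beta, atol=1e-10)

    def test_design_contains_main_effects_only(self):
        rng = np.random.default_rng(2)
        fit = fit_log_model(_toy_dataset(rng), "income")
        assert fit.param_names[0] == "intercept"
        assert all(name.count("[") == 1 for name in fit.param_names[1:])
        assert fit.reference_group == "ft_no_condition"

    def test_null_effects_ci_covers_zero_at_nominal_rate(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            data = _toy_dataset(rng, n=300, effects={"group": 0.0})
            fit = fit_log_model(data, "income")
            beta, se, _ = fit.coefficient("group", "nilf_diabetes")
            covered += abs(beta) <= 1.96 * se
        assert covered >= 93

    def test_offset_required_for_zeros(self):
        rng = np.random.default_rng(3)
        data = _toy_dataset(rng, n=50)
        data.loc[data.index[0], "income"] = 0.0
        with pytest.raises(ValueError, match="offset"):
            fit_log_model(data, "income")
        fit_log_model(data, "income", offset=1.0)  # shifted fit succeeds

    def test_collinear_design_names_aliased_columns(self):
        rng = np.random.default_rng(4)
        data = _toy_dataset(rng, n=50)
        data["education"] = np.where(data["sex"] == "male", "university", "non_university")
        with pytest.raises(ValueError, match="aliased"):
            fit_log_model(data, "income")

    def test_single_group_rejected(self):
        rng = np.random.default_rng(5)
        data = _toy_dataset(rng, n=30)
        with pytest.raises(ValueError, match="two groups"):
            fit_log_model(data[data["group"] == "ft_no_condition"], "income")

    def test_weighted_switch_changes_fit(self):
        rng = np.random.default_rng(6)
        data = _toy_dataset(rng, n=200, effects={"group": -0.5})
        unweighted = fit_log_model(data, "income")
        weighted = fit_log_model(data, "income", weights=rng.uniform(0.5, 5.0, len(data)))
        assert not np.allclose(unweighted.results.params, weighted.results.params)

    def test_group_effects_table_structure(self, matched_small):
        fit = fit_log_model(matched_small, "income")
        effects = group_effects(fit)
        assert "ft_no_condition" not in effects.index
        inside = (effects["ci_low"] <= effects["pct_diff"]) & (
            effects["pct_diff"] <= effects["ci_high"]
        )
        assert inside.all()
        assert (effects["pct_diff"] > -100).all()


class TestPercentDifference:
    def test_identity_and_doubling(self):
        assert percent_difference(0.0)[0] == 0.0
        assert percent_difference(np.log(2.0))[0] == pytest.approx(100.0)

    def test_large_negative_contrast(self):
        point, _ = percent_difference(np.log(0.117))
        assert round(point, 1) == -88.3

    def test_ci_encloses_point(self):
        point, (lo, hi) = percent_difference(-0.5, se=0.1)
        assert lo < point < hi

    @given(p=st.floats(-99.9, 1_000.0))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_round_trip_through_log_scale(self, p):
        beta = np.log(1.0 + p / 100.0)
        assert percent_difference(beta)[0] == pytest.approx(p, abs=1e-9)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.1, se=-1.0)


class TestDiagnostics:
    def test_normal_residuals_pass_at_nominal_rate(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(20_000 + seed)
            fit = fit_log_model(_toy_dataset(rng, n=200), "income")
            rejections += diagnostics(fit).normality_p < 0.05
        assert rejections <= 10

    def test_heavy_tailed_residuals_rejected_in_majority(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(30_000 + seed)
            data = _toy_dataset(rng, n=500)
            # replace log-scale noise with t(2) tails
            data["income"] = np.exp(np.log(data["income"]) + rng.standard_t(2, len(data)))
            fit = fit_log_model(data, "income")
            rejections += diagnostics(fit).normality_p < 0.05
        assert rejections > 10

    def test_perfect_fit_flagged_degenerate(self):
        data = pd.DataFrame(
            {
                "group": ["ft_no_condition"] * 4 + ["nilf_diabetes"] * 4,
                "age_group": ["45-49"] * 8,
                "sex": ["male"] * 8,
                "education": ["university"] * 8,
                "income": [100.0] * 4 + [50.0] * 4,
            }
        )
        fit = fit_log_model(data, "income", covariates=("group",))
        report = diagnostics(fit)
        assert report.degenerate
        assert np.isnan(report.normality_p)

    def test_qq_data_shapes_align(self):
        rng = np.random.default_rng(8)
        report = diagnostics(fit_log_model(_toy_dataset(rng, n=120), "income"))
        assert report.qq_theoretical.shape == report.qq_sample.shape == (120,)
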