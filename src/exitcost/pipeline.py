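"""End-to-end orchestration: generate, calibrate, match, model, aggregate.

A single :func:`run_pipeline` call executes the five stages in order, writes
every intermediate product as plain CSV/JSON into a run directory, and closes
with a manifest recording the configuration hash, stage seeds and a SHA-256
checksum of every output, so a rerun with the same configuration can be
verified byte-identical. Any stage can be re-executed in isolation from the
written CSVs through the stage functions themselves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .calibrate import calibrate_weights, check_benchmarks
from .categories import NILF_DIABETES
from .impact import (
    CounterfactualSpec,
    GDPParameters,
    NationalImpact,
    apply_preventable_fraction,
    counterfactual_economics,
    national_losses,
    reference_state_means,
)
from .match import DEFAULT_PRIORITY, impute_economics
from .model import diagnostics, fit_log_model, group_effects, summarize_by_group
from .synth import PopulationSpec, default_spec, generate_benchmarks, generate_donors, generate_survey, scaled_spec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

OUTCOME_OFFSETS = {"income": 0.0, "welfare": 1.0, "tax": 1.0}


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``seed`` drives per-stage seeds (survey, donors, match) unless explicit
    ``seeds`` are given. ``counterfactual`` of ``None`` derives the reference
    employment shares from the calibrated survey itself.
    """

    spec: PopulationSpec = dataclasses.field(default_factory=default_spec)
    seed: int = 0
    seeds: dict[str, int] | None = None
    n_donors: int = 20_000
    strata: tuple[str, ...] = ("age_group", "sex")
    bounds: tuple[float, float] = (0.3, 3.0)
    tol: float = 1e-6
    max_iter: int = 50
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    offsets: dict[str, float] = dataclasses.field(default_factory=lambda: dict(OUTCOME_OFFSETS))
    counterfactual: CounterfactualSpec | None = None
    counterfactual_method: str = "regression"
    gdp: GDPParameters = dataclasses.field(default_factory=GDPParameters)
    preventable_fraction: float = 0.89

    def stage_seeds(self) -> dict[str, int]:
        if self.seeds is not None:
            return dict(self.seeds)
        return {"survey": self.seed, "donors": self.seed + 1, "match": self.seed + 2}

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "seeds": self.stage_seeds(),
            "n_donors": self.n_donors,
            "strata": list(self.strata),
            "bounds": list(self.bounds),
            "tol": self.tol,
            "max_iter": self.max_iter,
            "priority": list(self.priority),
            "offsets": dict(self.offsets),
            "counterfactual": dataclasses.asdict(self.counterfactual) if self.counterfactual else None,
            "counterfactual_method": self.counterfactual_method,
            "gdp": dataclasses.asdict(self.gdp),
            "preventable_fraction": self.preventable_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        kwargs: dict = {}
        if "spec" in d and d["spec"] is not None:
            kwargs["spec"] = PopulationSpec.from_dict(d["spec"])
        elif "n_records" in d:  # convenience: scale the default spec
            kwargs["spec"] = scaled_spec(int(d["n_records"]), seed=int(d.get("seed", 0)))
        for key in ("seed", "n_donors", "max_iter"):
            if key in d:
                kwargs[key] = int(d[key])
        for key in ("tol", "preventable_fraction"):
            if key in d:
                kwargs[key] = float(d[key])
        if "seeds" in d and d["seeds"] is not None:
            kwargs["seeds"] = {k: int(v) for k, v in d["seeds"].items()}
        for key in ("strata", "priority"):
            if key in d:
                kwargs[key] = tuple(d[key])
        if "bounds" in d:
            kwargs["bounds"] = tuple(float(b) for b in d["bounds"])
        if "offsets" in d:
            kwargs["offsets"] = {k: float(v) for k, v in d["offsets"].items()}
        if d.get("counterfactual"):
            kwargs["counterfactual"] = CounterfactualSpec(**{k: float(v) for k, v in d["counterfactual"].items()})
        if "counterfactual_method" in d:
            kwargs["counterfactual_method"] = d["counterfactual_method"]
        if "gdp" in d and d["gdp"] is not None:
            kwargs["gdp"] = GDPParameters(**{k: float(v) for k, v in d["gdp"].items()})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _write_csv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages, write outputs under ``out_dir``, return key results.

    Outputs: survey.csv, benchmarks.csv, calibration.json, donors.csv,
    matched.csv, match_report.json, table1.{csv,json}, table2.{csv,json},
    table3.{csv,json} and manifest.json. Returns a dict with the in-memory
    results (summary, effects, impacts) and the output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    paths: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("synth"):
        config.spec.validate()
        survey = generate_survey(config.spec, seed=seeds["survey"])
        benchmarks = generate_benchmarks(config.spec, list(config.strata))
        donors = generate_donors(config.spec, config.n_donors, seed=seeds["donors"])
        _write_csv(paths.setdefault("survey", out / "survey.csv"), survey)
        _write_csv(paths.setdefault("benchmarks", out / "benchmarks.csv"), benchmarks.to_frame())
        _write_csv(paths.setdefault("donors", out / "donors.csv"), donors)

    with stage("calibrate"):
        result = calibrate_weights(
            survey, benchmarks, bounds=config.bounds, tol=config.tol, max_iter=config.max_iter
        )
        survey = survey.assign(weight=result.weights)
        report = check_benchmarks(survey, result.weights, benchmarks, tol=config.tol)
        _write_json(
            paths.setdefault("calibration", out / "calibration.json"),
            {
                "iterations": result.iterations,
                "max_constraint_violation": result.max_constraint_violation,
                "truncated_count": result.truncated_count,
                "converged": result.converged,
                "cells_ok": int(report["ok"].sum()),
                "cells_total": int(len(report)),
            },
        )

    with stage("match"):
        matched, match_report = impute_economics(
            survey, donors, priority=config.priority, seed=seeds["match"]
        )
        _write_csv(paths.setdefault("matched", out / "matched.csv"), matched)
        _write_json(paths.setdefault("match_report", out / "match_report.json"), match_report.to_dict())

    with stage("model"):
        table1 = summarize_by_group(matched, weight_col="weight")
        _write_csv(paths.setdefault("table1_csv", out / "table1.csv"), table1, index=True)
        _write_json(paths.setdefault("table1", out / "table1.json"), table1.reset_index().to_dict("records"))
        fits, effects_json = {}, {}
        for outcome, offset in config.offsets.items():
            fits[outcome] = fit_log_model(matched, outcome, offset=offset)
            eff = group_effects(fits[outcome])
            diag = diagnostics(fits[outcome])
            effects_json[outcome] = {
                "reference": fits[outcome].reference_group,
                "offset": offset,
                "effects": eff.reset_index().to_dict("records"),
                "diagnostics": {
                    "normality_p": diag.normality_p,
                    "heteroscedasticity_p": diag.het_p,
                    "degenerate": diag.degenerate,
                },
            }
        table2 = pd.concat(
            {o: group_effects(fits[o]) for o in fits}, names=["outcome", "group"]
        ).reset_index()
        _write_csv(paths.setdefault("table2_csv", out / "table2.csv"), table2)
        _write_json(paths.setdefault("table2", out / "table2.json"), effects_json)

    with stage("impact"):
        cf_spec = config.counterfactual or CounterfactualSpec.from_survey(survey)
        nilf = matched[matched["group"] == NILF_DIABETES]
        ref_means = reference_state_means(matched) if config.counterfactual_method == "group_mean" else None
        losses = counterfactual_economics(
            nilf, fits, cf_spec, method=config.counterfactual_method, reference_means=ref_means
        )
        base = national_losses(losses, nilf["weight"], gdp_params=config.gdp, scenario="base")
        preventable = apply_preventable_fraction(base, config.preventable_fraction)
        table3 = pd.DataFrame([base.rounded().to_dict(), preventable.to_dict()])
        _write_csv(paths.setdefault("table3_csv", out / "table3.csv"), table3)
        _write_json(
            paths.setdefault("table3", out / "table3.json"),
            {
                "base": base.rounded().to_dict(),
                "preventable": preventable.to_dict(),
                "counterfactual": dataclasses.asdict(cf_spec),
                "preventable_fraction": config.preventable_fraction,
            },
        )

    config_dump = config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": config_dump,
        "config_hash": hashlib.sha256(
            json.dumps(config_dump, sort_keys=True, default=float).encode()
        ).hexdigest(),
        "seeds": seeds,
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)} for name, p in paths.items()},
    }
    _write_json(out / "manifest.json", manifest)

    return {
        "paths": {name: p for name, p in paths.items()} | {"manifest": out / "manifest.json"},
        "summary": table1,
        "effects": {o: group_effects(fits[o]) for o in fits},
        "base_impact": base,
        "preventable_impact": preventable,
        "calibration": result,
        "match_report": match_report,
    }
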