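"""Pipeline orchestration: simulate → metrics → stepwise → report bundle."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

import dosegap
from dosegap.io import (
    CohortPaths,
    CohortValidationError,
    read_cohort,
    schema_from_config,
    validate_cohort_files,
    write_cohort,
)
from dosegap.metrics import (
    WindowPolicy,
    evaluate_patient,
    sensitivity_grid,
    summarize_proportion,
)
from dosegap.model import (
    SelectionThresholds,
    SeparationError,
    StepwiseResult,
    covariates_from_schema,
    stepwise_select,
    table2_report,
)
from dosegap.synthetic import SimulationConfig, SyntheticCohort, generate_cohort

__all__ = [
    "RunConfig",
    "ValidationReport",
    "run_pipeline",
    "validate_inputs",
    "compute_outcomes",
    "analysis_frame",
    "analyze_stratum",
]


class RunConfig(BaseModel):
    """Everything a pipeline run needs; either simulate or read a cohort."""

    simulate: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    out_dir: str
    nominal_interval_days: int = 183
    persistence_allowance_days: int = 56
    adherence_tolerance_days: int = 28
    p_enter: float = 0.25
    p_stay: float = 0.30
    p_significant: float = 0.05
    horizon_days: int = Field(default=731, gt=0)
    required_injections: int = 4
    strata: Optional[list[str]] = None
    ci_method: str = "wilson"
    seed: Optional[int] = None

    def policy(self) -> WindowPolicy:
        return WindowPolicy(
            nominal_interval_days=self.nominal_interval_days,
            persistence_allowance_days=self.persistence_allowance_days,
            adherence_tolerance_days=self.adherence_tolerance_days,
        )

    def thresholds(self) -> SelectionThresholds:
        return SelectionThresholds(
            p_enter=self.p_enter, p_stay=self.p_stay, p_significant=self.p_significant
        )


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(paths: CohortPaths | Path | str) -> ValidationReport:
    """Validate cohort files; returns per-violation messages with context."""
    if not isinstance(paths, CohortPaths):
        paths = CohortPaths.in_dir(paths)
    return ValidationReport(violations=tuple(validate_cohort_files(paths)))


def compute_outcomes(
    cohort: SyntheticCohort,
    policy: WindowPolicy | None = None,
    required_injections: int = 4,
    horizon_days: int = 731,
) -> pd.DataFrame:
    """Per-patient outcome table: persistence/adherence flags and MCR."""
    policy = policy or WindowPolicy()
    rows = []
    for history, cov in zip(cohort.histories, cohort.covariates):
        outcome = evaluate_patient(history, policy, required_injections, horizon_days)
        rows.append(
            {
                "patient_id": outcome.patient_id,
                "stratum": cov.stratum,
                "persistent_24m": int(outcome.persistent_24m),
                "adherent_24m": int(outcome.adherent_24m),
                "mcr_percent": outcome.mcr_percent,
                "n_injections": outcome.n_injections,
            }
        )
    return pd.DataFrame(rows)


def analysis_frame(cohort: SyntheticCohort, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Outcomes joined with one column per covariate (NaN = missing)."""
    cov_rows = []
    for cov in cohort.covariates:
        row: dict[str, Any] = {"patient_id": cov.patient_id}
        row.update(cov.values)
        cov_rows.append(row)
    covs = pd.DataFrame(cov_rows)
    return outcomes.merge(covs, on="patient_id", validate="one_to_one")


def _mean_ci(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, math.nan, math.nan
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    tcrit = float(stats.t.ppf(1 - alpha / 2, len(values) - 1))
    return mean, mean - tcrit * sem, mean + tcrit * sem


def analyze_stratum(
    frame: pd.DataFrame,
    candidates,
    thresholds: SelectionThresholds,
    outcome: str = "persistent_24m",
) -> dict[str, Any]:
    """Stepwise model + per-level report for one stratum's joined frame.

    Returns a JSON-serialisable dict; on a degenerate stratum (single
    outcome class, no usable candidates) the dict carries an ``error``
    entry instead of a model.
    """
    try:
        result = stepwise_select(frame, outcome, candidates, thresholds)
    except (ValueError, SeparationError) as exc:
        return {"error": str(exc), "n_patients": len(frame)}
    summary = result.summary_frame()
    report = table2_report(frame, outcome, result)
    return {
        "selected": list(result.selected),
        "n_complete_cases": result.n_complete_cases,
        "coefficients": {t: float(c) for t, c in result.coefficients.items()},
        "terms": summary.to_dict(orient="records"),
        "trace": [
            {"step": t.step, "action": t.action, "covariate": t.covariate, "p_value": t.p_value}
            for t in result.trace
        ],
        "table2": report.to_dict(orient="records"),
        "thresholds": {
            "p_enter": thresholds.p_enter,
            "p_stay": thresholds.p_stay,
            "p_significant": thresholds.p_significant,
        },
    }


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, lineterminator="\n")


def _config_hash(config: RunConfig) -> str:
    # hash only analysis-relevant settings, not where the bundle lands
    payload = config.model_dump(mode="json", exclude={"out_dir", "input_dir"})
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the report bundle to ``out_dir``.

    The bundle contains per-patient outcomes, per-stratum persistence /
    adherence / MCR summaries with 95% CIs, the sensitivity-window grid,
    one stepwise-model JSON (with per-level breakdown and forest-plot CSV)
    per stratum, and a manifest recording the config hash, seed, and
    package version.  Identical configs produce identical bundles.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if (config.simulate is None) == (config.input_dir is None):
        raise ValueError("exactly one of 'simulate' and 'input_dir' must be set")
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim = sim.model_copy(update={"seed": config.seed})
        cohort = generate_cohort(sim)
        schema = schema_from_config(sim)
        write_cohort(cohort, out_dir / "cohort", schema)
    else:
        paths = CohortPaths.in_dir(config.input_dir)
        report = validate_inputs(paths)
        if not report.ok:
            raise CohortValidationError(list(report.violations))
        cohort = read_cohort(paths)
        schema = _load_schema_dict(paths.schema)

    policy = config.policy()
    outcomes = compute_outcomes(cohort, policy, config.required_injections, config.horizon_days)
    frame = analysis_frame(cohort, outcomes)

    available = sorted(outcomes["stratum"].unique())
    strata = config.strata or available
    unknown = sorted(set(strata) - set(available))
    if unknown:
        raise ValueError(f"unknown stratum label(s): {unknown}; available: {available}")

    _write_csv(outcomes.sort_values("patient_id"), out_dir / "outcomes.csv")

    stratum_of = dict(zip(frame["patient_id"], frame["stratum"]))
    summary_rows = []
    grid_frames = []
    for label in ["ALL", *strata]:
        sub = frame if label == "ALL" else frame[frame["stratum"] == label]
        if sub.empty:
            raise ValueError(f"empty stratum: {label!r}")
        n = len(sub)
        for metric in ("persistent_24m", "adherent_24m"):
            s = summarize_proportion(int(sub[metric].sum()), n, method=config.ci_method)
            summary_rows.append(
                {
                    "stratum": label,
                    "metric": {"persistent_24m": "persistence", "adherent_24m": "adherence"}[metric],
                    "n_success": s.n_success,
                    "n_total": s.n_total,
                    "value": s.proportion_percent,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                }
            )
        mean, low, high = _mean_ci(sub["mcr_percent"].to_numpy())
        summary_rows.append(
            {
                "stratum": label,
                "metric": "mcr_mean",
                "n_success": "",
                "n_total": n,
                "value": mean,
                "ci95_low": low,
                "ci95_high": high,
            }
        )
        histories = [
            h for h in cohort.histories
            if label == "ALL" or stratum_of[h.patient_id] == label
        ]
        grid = sensitivity_grid(histories, policy, config.required_injections,
                                ci_method=config.ci_method)
        grid.insert(0, "stratum", label)
        grid_frames.append(grid)

    _write_csv(pd.DataFrame(summary_rows), out_dir / "summary.csv")
    _write_csv(pd.concat(grid_frames, ignore_index=True), out_dir / "sensitivity_grid.csv")

    candidates = covariates_from_schema(schema)
    thresholds = config.thresholds()
    models: dict[str, Any] = {}
    for label in strata:
        sub = frame[frame["stratum"] == label]
        model = analyze_stratum(sub, candidates, thresholds)
        models[label] = model
        safe = label.replace("/", "_").replace(" ", "_")
        with open(out_dir / f"stepwise_{safe}.json", "w") as fh:
            json.dump(model, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if "table2" in model:
            _write_csv(pd.DataFrame(model["table2"]), out_dir / f"table2_{safe}.csv")
            forest = pd.DataFrame(model["terms"])
            forest = forest[forest["term"] != "(intercept)"]
            _write_csv(
                forest[["term", "odds_ratio", "or_ci_low", "or_ci_high", "wald_p"]].rename(
                    columns={"term": "level", "odds_ratio": "or",
                             "or_ci_low": "ci_low", "or_ci_high": "ci_high"}
                ),
                out_dir / f"forest_{safe}.csv",
            )

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.simulate.seed if config.simulate is not None else config.seed,
        "version": dosegap.__version__,
        "n_patients": len(cohort),
        "strata": strata,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "out_dir": str(out_dir),
        "manifest": manifest,
        "summary": pd.DataFrame(summary_rows),
        "models": models,
    }


def _load_schema_dict(path: Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
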