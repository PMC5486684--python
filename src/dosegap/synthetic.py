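"""Synthetic cohort generator with a discrete-hazard continuation model.

Each patient starts therapy at day 0.  Before every subsequent scheduled
injection a Bernoulli draw with probability
``logistic(baseline_continuation_logit + sum of the patient's covariate
contributions)`` decides whether the injection is received; once a patient
discontinues, no further injections occur.  Received injections are delayed
relative to the 183-day schedule by a jitter draw, truncated so gaps stay
positive.  The per-step logistic structure makes covariate effects directly
interpretable as per-step odds ratios and induces monotone attrition.

Randomness is driven by one global seed spawning an independent substream
per patient index, so cohorts are reproducible under re-ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from dosegap.metrics import InjectionHistory

__all__ = [
    "CovariateSpec",
    "GapJitterSpec",
    "SimulationConfig",
    "PatientCovariates",
    "SyntheticCohort",
    "generate_cohort",
    "default_study_config",
]

NOMINAL_GAP_DAYS = 183


class CovariateSpec(BaseModel):
    """Declares one baseline covariate to simulate.

    Binary covariates take values 0/1 with the given prevalence; categorical
    covariates draw one of ``levels`` with ``probabilities``.
    """

    name: str
    type: Literal["binary", "categorical"]
    prevalence: Optional[float] = None
    levels: Optional[list[str]] = None
    probabilities: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "CovariateSpec":
        if self.type == "binary":
            if self.prevalence is None or not 0.0 <= self.prevalence <= 1.0:
                raise ValueError(f"covariate {self.name!r}: binary prevalence must be in [0, 1]")
        else:
            if not self.levels or not self.probabilities:
                raise ValueError(f"covariate {self.name!r}: categorical needs levels and probabilities")
            if len(self.levels) != len(self.probabilities):
                raise ValueError(f"covariate {self.name!r}: levels/probabilities length mismatch")
            if any(p < 0 or p > 1 for p in self.probabilities):
                raise ValueError(f"covariate {self.name!r}: probabilities must be in [0, 1]")
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise ValueError(f"covariate {self.name!r}: probabilities must sum to 1")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"covariate {self.name!r}: duplicate levels")
        return self


class GapJitterSpec(BaseModel):
    """Distribution of the delay of each received injection vs. schedule.

    Families:

    * ``none`` — zero jitter, gaps of exactly 183 days.
    * ``truncated_normal`` — normal(mean, sd) truncated to [low, high];
      defaults keep every continuing patient inside the default persistence
      window.
    * ``heavy_tail`` — with probability ``late_prob`` a uniform late
      component on [late_low, late_high] days, otherwise the truncated
      normal; creates late-but-continuing patients that separate the
      sensitivity windows.
    """

    family: Literal["none", "truncated_normal", "heavy_tail"] = "truncated_normal"
    mean: float = 0.0
    sd: float = 10.0
    low: float = -28.0
    high: float = 56.0
    late_prob: float = 0.3
    late_low: float = 57.0
    late_high: float = 120.0

    @model_validator(mode="after")
    def _check(self) -> "GapJitterSpec":
        for name in ("mean", "sd", "low", "high", "late_prob", "late_low", "late_high"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"gap_jitter.{name} must be finite")
        if self.sd < 0:
            raise ValueError("gap_jitter.sd must be non-negative")
        if self.low > self.high:
            raise ValueError("gap_jitter.low must not exceed gap_jitter.high")
        if not 0.0 <= self.late_prob <= 1.0:
            raise ValueError("gap_jitter.late_prob must be in [0, 1]")
        if self.late_low > self.late_high:
            raise ValueError("gap_jitter.late_low must not exceed late_high")
        return self

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "none":
            return 0.0
        if self.family == "heavy_tail" and rng.random() < self.late_prob:
            return float(rng.uniform(self.late_low, self.late_high))
        if self.sd == 0.0:
            return float(min(max(self.mean, self.low), self.high))
        while True:  # rejection sampling; acceptance is high for the defaults
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)


class SimulationConfig(BaseModel):
    """Full description of a synthetic cohort, including the ground truth.

    ``true_log_odds`` maps a covariate key to its additive contribution to
    the log-odds of continuing at each scheduled injection.  Keys are the
    bare covariate name for binary covariates (applied when the value is 1),
    ``"name=level"`` for categorical levels, and ``"stratum=label"`` for
    stratum effects.
    """

    n_patients: int = Field(gt=0)
    strata: list[tuple[str, float]] = Field(default_factory=lambda: [("ALL", 1.0)])
    covariate_specs: list[CovariateSpec] = Field(default_factory=list)
    true_log_odds: dict[str, float] = Field(default_factory=dict)
    baseline_continuation_logit: float = 2.5
    gap_jitter: GapJitterSpec = Field(default_factory=GapJitterSpec)
    observation_days: int = 731
    n_scheduled_injections: int = 4
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.strata:
            raise ValueError("at least one stratum is required")
        fractions = [f for _, f in self.strata]
        if any(f < 0 or f > 1 for f in fractions):
            raise ValueError("stratum fractions must be in [0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"stratum fractions must sum to 1, got {sum(fractions)}")
        if len({label for label, _ in self.strata}) != len(self.strata):
            raise ValueError("duplicate stratum labels")
        if self.observation_days <= 0:
            raise ValueError("observation_days must be positive")
        if self.n_scheduled_injections < 1:
            raise ValueError("n_scheduled_injections must be at least 1")
        names = [s.name for s in self.covariate_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        for value in self.true_log_odds.values():
            if math.isnan(value):
                raise ValueError("true_log_odds values must not be NaN")
        return self

    def known_keys(self) -> set[str]:
        keys = {f"stratum={label}" for label, _ in self.strata}
        for spec in self.covariate_specs:
            if spec.type == "binary":
                keys.add(spec.name)
            else:
                keys.update(f"{spec.name}={level}" for level in spec.levels or [])
        return keys


@dataclass(frozen=True)
class PatientCovariates:
    """Baseline covariates for one patient.

    ``values`` maps covariate name to its value: 0/1 ints for binary
    covariates, level strings for categorical ones, numbers for scores and
    counts.  ``None`` marks missing data.  The canonical study covariates
    (age group, smoking, comorbidity index, fall/fracture/immobility
    history, prior-therapy flags, prescribing reasons, MMAS-8 score,
    concomitant-medication count) live under their schema names.
    """

    patient_id: str
    stratum: str
    values: Mapping[str, Any] = field(default_factory=dict)

    def get(self, name: str, default: Any = None) -> Any:
        return self.values.get(name, default)


@dataclass(frozen=True)
class SyntheticCohort:
    histories: tuple[InjectionHistory, ...]
    covariates: tuple[PatientCovariates, ...]
    truth: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        if len(self.histories) != len(self.covariates):
            raise ValueError("histories and covariates must have equal length")
        for h, c in zip(self.histories, self.covariates):
            if h.patient_id != c.patient_id:
                raise ValueError(f"patient id mismatch: {h.patient_id} vs {c.patient_id}")
            if h.injection_days[0] != 0:
                raise ValueError(f"{h.patient_id}: first injection must be at day 0")

    def __len__(self) -> int:
        return len(self.histories)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x)) if x < 700 else 1.0
    z = math.exp(x)
    return z / (1.0 + z)


def _continuation_logit(config: SimulationConfig, stratum: str, values: Mapping[str, Any]) -> float:
    logit = config.baseline_continuation_logit
    logit += config.true_log_odds.get(f"stratum={stratum}", 0.0)
    for spec in config.covariate_specs:
        value = values.get(spec.name)
        if spec.type == "binary":
            if value:
                logit += config.true_log_odds.get(spec.name, 0.0)
        else:
            logit += config.true_log_odds.get(f"{spec.name}={value}", 0.0)
    return logit


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a cohort under the discrete-hazard continuation model.

    Identical configs (including the seed) produce identical cohorts.
    Injections whose jittered date would fall beyond ``observation_days``
    are not observed; every patient's observation ends at
    ``observation_days``.
    """
    unknown = set(config.true_log_odds) - config.known_keys()
    if unknown:
        raise ValueError(f"true_log_odds refers to unknown covariate keys: {sorted(unknown)}")

    labels = [label for label, _ in config.strata]
    fractions = np.asarray([f for _, f in config.strata], dtype=float)
    fractions = fractions / fractions.sum()

    width = max(5, len(str(config.n_patients)))
    histories: list[InjectionHistory] = []
    covariates: list[PatientCovariates] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        pid = f"P{i:0{width}d}"
        stratum = labels[int(rng.choice(len(labels), p=fractions))]
        values: dict[str, Any] = {}
        for spec in config.covariate_specs:
            if spec.type == "binary":
                values[spec.name] = int(rng.random() < spec.prevalence)
            else:
                idx = int(rng.choice(len(spec.levels), p=np.asarray(spec.probabilities)))
                values[spec.name] = spec.levels[idx]

        p_continue = _logistic(_continuation_logit(config, stratum, values))
        days = [0]
        for _ in range(2, config.n_scheduled_injections + 1):
            if rng.random() >= p_continue:
                break
            gap = NOMINAL_GAP_DAYS + config.gap_jitter.draw(rng)
            gap = max(1, int(round(gap)))
            day = days[-1] + gap
            if day > config.observation_days:
                break
            days.append(day)

        histories.append(
            InjectionHistory(
                patient_id=pid,
                injection_days=tuple(days),
                observation_end_day=config.observation_days,
            )
        )
        covariates.append(PatientCovariates(patient_id=pid, stratum=stratum, values=values))

    return SyntheticCohort(
        histories=tuple(histories),
        covariates=tuple(covariates),
        truth=config.model_copy(deep=True),
    )


def default_study_config(n_patients: int = 1500, seed: int = 0) -> SimulationConfig:
    """A cohort shaped like the study: four country strata, ~183-day dosing,
    24-month observation, and baseline covariates at roughly the published
    prevalences, with a recent fall and high comorbidity lowering the
    per-step continuation odds."""
    specs = [
        CovariateSpec(
            name="age_group",
            type="categorical",
            levels=["<65", "65-<75", ">=75"],
            probabilities=[0.28, 0.35, 0.37],
        ),
        CovariateSpec(
            name="smoking",
            type="categorical",
            levels=["never", "former", "current"],
            probabilities=[0.74, 0.10, 0.16],
        ),
        CovariateSpec(name="mwci_above_median", type="binary", prevalence=0.45),
        CovariateSpec(name="chronic_condition", type="binary", prevalence=0.83),
        CovariateSpec(name="fall_12m", type="binary", prevalence=0.18),
        CovariateSpec(name="ge2_historical_fractures", type="binary", prevalence=0.17),
        CovariateSpec(name="hip_fracture_history", type="binary", prevalence=0.05),
        CovariateSpec(name="immobility_12m", type="binary", prevalence=0.08),
        CovariateSpec(name="prior_pmo_12m", type="binary", prevalence=0.75),
        CovariateSpec(
            name="discontinued_prior_pmo",
            type="categorical",
            levels=["no", "yes", "n/a"],
            probabilities=[0.68, 0.17, 0.15],
        ),
        CovariateSpec(name="reason_failed_prior", type="binary", prevalence=0.35),
        CovariateSpec(name="reason_multiple_risk", type="binary", prevalence=0.42),
        CovariateSpec(name="reason_intolerant", type="binary", prevalence=0.22),
        CovariateSpec(name="meds_above_median", type="binary", prevalence=0.44),
        CovariateSpec(
            name="mmas8_category",
            type="categorical",
            levels=["high", "medium", "low"],
            probabilities=[0.50, 0.33, 0.17],
        ),
    ]
    return SimulationConfig(
        n_patients=n_patients,
        strata=[("Germany", 0.39), ("Austria", 0.20), ("Greece", 0.21), ("Belgium", 0.20)],
        covariate_specs=specs,
        true_log_odds={
            "fall_12m": math.log(0.6),
            "mwci_above_median": math.log(0.75),
            "immobility_12m": math.log(0.55),
            "age_group=>=75": math.log(0.7),
            "chronic_condition": math.log(1.4),
        },
        baseline_continuation_logit=2.6,
        gap_jitter=GapJitterSpec(family="truncated_normal", sd=16.0),
        observation_days=731,
        n_scheduled_injections=4,
        seed=seed,
    )
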