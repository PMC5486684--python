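"""Gap-window persistence/adherence classification and coverage metrics.

All date arithmetic is done on integer day offsets from the first injection
(day 0).  Six months are operationalised as 183 days and a week as 7 days
throughout; calendar dates exist only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DAYS_PER_WEEK",
    "InjectionHistory",
    "WindowPolicy",
    "PersistenceOutcome",
    "ProportionSummary",
    "classify_persistence",
    "classify_adherence",
    "compute_mcr",
    "evaluate_patient",
    "summarize_proportion",
    "sensitivity_grid",
    "categorize_mmas",
    "round_percent",
    "PERSISTENCE_WINDOW_WEEKS",
    "ADHERENCE_WINDOW_WEEKS",
]

DAYS_PER_WEEK = 7

#: Sensitivity-analysis window grid, in weeks of allowance / tolerance.
PERSISTENCE_WINDOW_WEEKS = (4, 6, 8, 12)
ADHERENCE_WINDOW_WEEKS = (4, 6, 8, 12)


def round_percent(value: float, ndigits: int = 1) -> float:
    """Round a percentage for reporting using half-up rounding.

    Python's builtin :func:`round` uses banker's rounding; reported
    percentages follow the conventional half-up rule instead.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class InjectionHistory:
    """One patient's ordered injection dates and observation window.

    Parameters
    ----------
    patient_id:
        Opaque identifier.
    injection_days:
        Strictly increasing integer day offsets; the first must be 0.
    observation_end_day:
        End of follow-up or withdrawal, as a day offset; must be at least
        the last injection day.
    """

    patient_id: str
    injection_days: tuple[int, ...]
    observation_end_day: int

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.injection_days)
        object.__setattr__(self, "injection_days", days)
        if not days:
            raise ValueError(f"{self.patient_id}: at least one injection is required")
        if days[0] != 0:
            raise ValueError(f"{self.patient_id}: first injection must be at day 0, got {days[0]}")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.patient_id}: injection days must be strictly increasing: {days}")
        if self.observation_end_day < days[-1]:
            raise ValueError(
                f"{self.patient_id}: observation_end_day ({self.observation_end_day}) "
                f"precedes last injection day ({days[-1]})"
            )

    @property
    def gaps(self) -> tuple[int, ...]:
        """Consecutive inter-injection gaps in days."""
        return tuple(b - a for a, b in zip(self.injection_days, self.injection_days[1:]))

    @property
    def n_injections(self) -> int:
        return len(self.injection_days)


@dataclass(frozen=True)
class WindowPolicy:
    """Nominal dosing interval plus the permissible-gap windows.

    ``persistence_allowance_days`` is the one-sided grace added to the
    nominal interval (default 8 weeks = 56 days); ``adherence_tolerance_days``
    the symmetric tolerance around it (default 4 weeks = 28 days).
    """

    nominal_interval_days: int = 183
    persistence_allowance_days: int = 8 * DAYS_PER_WEEK
    adherence_tolerance_days: int = 4 * DAYS_PER_WEEK

    def __post_init__(self) -> None:
        if self.nominal_interval_days <= 0:
            raise ValueError("nominal_interval_days must be positive")
        if self.persistence_allowance_days <= 0:
            raise ValueError("persistence_allowance_days must be positive")
        if self.adherence_tolerance_days <= 0:
            raise ValueError("adherence_tolerance_days must be positive")
        if self.adherence_tolerance_days >= self.nominal_interval_days:
            raise ValueError("adherence_tolerance_days must be smaller than the nominal interval")

    @classmethod
    def from_weeks(
        cls,
        nominal_interval_days: int = 183,
        persistence_allowance_weeks: int = 8,
        adherence_tolerance_weeks: int = 4,
    ) -> "WindowPolicy":
        return cls(
            nominal_interval_days=nominal_interval_days,
            persistence_allowance_days=persistence_allowance_weeks * DAYS_PER_WEEK,
            adherence_tolerance_days=adherence_tolerance_weeks * DAYS_PER_WEEK,
        )

    @property
    def persistence_limit_days(self) -> int:
        return self.nominal_interval_days + self.persistence_allowance_days

    @property
    def adherence_bounds_days(self) -> tuple[int, int]:
        return (
            self.nominal_interval_days - self.adherence_tolerance_days,
            self.nominal_interval_days + self.adherence_tolerance_days,
        )


@dataclass(frozen=True)
class PersistenceOutcome:
    """Per-patient classification under one :class:`WindowPolicy`."""

    patient_id: str
    persistent_24m: bool
    adherent_24m: bool
    mcr_percent: float
    n_injections: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mcr_percent <= 100.0:
            raise ValueError(f"mcr_percent out of [0, 100]: {self.mcr_percent}")


@dataclass(frozen=True)
class ProportionSummary:
    """A success proportion with a clipped 95% confidence interval.

    ``proportion_percent`` is rounded to one decimal for reporting;
    ``n_success``/``n_total`` retain the exact counts.
    """

    n_success: int
    n_total: int
    proportion_percent: float
    ci95_low: float
    ci95_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_success <= self.n_total:
            raise ValueError(f"need 0 <= n_success <= n_total, got {self.n_success}/{self.n_total}")


def _check_required(required_injections: int) -> None:
    if required_injections < 2:
        raise ValueError("required_injections must be at least 2 (persistence needs a gap)")


def classify_persistence(
    history: InjectionHistory,
    policy: WindowPolicy | None = None,
    required_injections: int = 4,
) -> bool:
    """True iff every consecutive gap among the first ``required_injections``
    injections is within the nominal interval plus the allowance (inclusive).

    A patient with fewer than ``required_injections`` injections is
    non-persistent.  Injections beyond the required count are ignored.
    """
    policy = policy or WindowPolicy()
    _check_required(required_injections)
    if history.n_injections < required_injections:
        return False
    limit = policy.persistence_limit_days
    gaps = history.gaps[: required_injections - 1]
    return all(gap <= limit for gap in gaps)


def classify_adherence(
    history: InjectionHistory,
    policy: WindowPolicy | None = None,
    required_injections: int = 4,
) -> bool:
    """True iff every consecutive gap among the first ``required_injections``
    injections lies within nominal ± tolerance, bounds inclusive."""
    policy = policy or WindowPolicy()
    _check_required(required_injections)
    if history.n_injections < required_injections:
        return False
    low, high = policy.adherence_bounds_days
    gaps = history.gaps[: required_injections - 1]
    return all(low <= gap <= high for gap in gaps)


def compute_mcr(
    history: InjectionHistory,
    policy: WindowPolicy | None = None,
    horizon_days: int = 731,
) -> float:
    """Medication coverage ratio as a percentage of observed time covered.

    Each injection at day ``d`` covers the half-open interval
    ``[d, d + nominal_interval_days)``.  Coverage is the length of the union
    of those intervals intersected with ``[0, T)`` where
    ``T = min(horizon_days, observation_end_day)``; the result is
    ``100 * coverage / T``, so overlapping coverage from early re-injection
    is never double-counted and the ratio cannot exceed 100.
    """
    policy = policy or WindowPolicy()
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    if history.observation_end_day <= 0:
        raise ValueError("observation_end_day must be positive to define a denominator")
    end = min(horizon_days, history.observation_end_day)
    span = policy.nominal_interval_days
    covered = 0
    cursor = 0  # injections are sorted, so a single sweep suffices
    for day in history.injection_days:
        lo = max(day, cursor, 0)
        hi = min(day + span, end)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return 100.0 * covered / end


def evaluate_patient(
    history: InjectionHistory,
    policy: WindowPolicy | None = None,
    required_injections: int = 4,
    horizon_days: int = 731,
) -> PersistenceOutcome:
    """Bundle persistence, adherence, and MCR for one patient."""
    policy = policy or WindowPolicy()
    return PersistenceOutcome(
        patient_id=history.patient_id,
        persistent_24m=classify_persistence(history, policy, required_injections),
        adherent_24m=classify_adherence(history, policy, required_injections),
        mcr_percent=compute_mcr(history, policy, horizon_days),
        n_injections=history.n_injections,
    )


def summarize_proportion(
    n_success: int,
    n_total: int,
    method: str = "wilson",
) -> ProportionSummary:
    """Proportion as a percentage (one decimal) with a 95% CI.

    ``method`` is ``"wilson"`` (default; well behaved near 0 and 1) or
    ``"wald"`` (normal approximation, for comparability).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_success <= n_total:
        raise ValueError(f"need 0 <= n_success <= n_total, got {n_success}/{n_total}")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method: {method!r}")
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(n_success, n_total, alpha=0.05, method=sm_method)
    return ProportionSummary(
        n_success=int(n_success),
        n_total=int(n_total),
        proportion_percent=round_percent(100.0 * n_success / n_total),
        ci95_low=max(0.0, 100.0 * float(low)),
        ci95_high=min(100.0, 100.0 * float(high)),
    )


def sensitivity_grid(
    histories: Iterable[InjectionHistory],
    base_policy: WindowPolicy | None = None,
    required_injections: int = 4,
    persistence_weeks: Sequence[int] = PERSISTENCE_WINDOW_WEEKS,
    adherence_weeks: Sequence[int] = ADHERENCE_WINDOW_WEEKS,
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """Persistence/adherence proportions across the sensitivity window grid.

    Returns one row per (metric, window) cell with the summary counts,
    percentage, and CI.  Enlarging the window can only add successes, so
    each metric's column of proportions is non-decreasing in the window.
    """
    base_policy = base_policy or WindowPolicy()
    cohort = list(histories)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    for weeks in persistence_weeks:
        policy = WindowPolicy(
            nominal_interval_days=base_policy.nominal_interval_days,
            persistence_allowance_days=weeks * DAYS_PER_WEEK,
            adherence_tolerance_days=base_policy.adherence_tolerance_days,
        )
        n_yes = sum(classify_persistence(h, policy, required_injections) for h in cohort)
        summary = summarize_proportion(n_yes, len(cohort), method=ci_method)
        rows.append(("persistence", weeks, weeks * DAYS_PER_WEEK, summary))
    for weeks in adherence_weeks:
        policy = WindowPolicy(
            nominal_interval_days=base_policy.nominal_interval_days,
            persistence_allowance_days=base_policy.persistence_allowance_days,
            adherence_tolerance_days=weeks * DAYS_PER_WEEK,
        )
        n_yes = sum(classify_adherence(h, policy, required_injections) for h in cohort)
        summary = summarize_proportion(n_yes, len(cohort), method=ci_method)
        rows.append(("adherence", weeks, weeks * DAYS_PER_WEEK, summary))
    return pd.DataFrame(
        {
            "metric": [r[0] for r in rows],
            "window_weeks": [r[1] for r in rows],
            "window_days": [r[2] for r in rows],
            "n_success": [r[3].n_success for r in rows],
            "n_total": [r[3].n_total for r in rows],
            "proportion_percent": [r[3].proportion_percent for r in rows],
            "ci95_low": [r[3].ci95_low for r in rows],
            "ci95_high": [r[3].ci95_high for r in rows],
        }
    )


def categorize_mmas(score: float) -> str:
    """Map an MMAS-8 score to its adherence category.

    A score of 8 is ``high``, 6 to below 8 is ``medium``, below 6 is ``low``.
    """
    if not 0 <= score <= 8:
        raise ValueError(f"MMAS-8 score must be in [0, 8], got {score}")
    if score == 8:
        return "high"
    if score >= 6:
        return "medium"
    return "low"
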