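"""Logistic regression by IRLS and p-value threshold stepwise selection.

The selection procedure alternates forward and backward steps.  A candidate
enters when its likelihood-ratio p-value against the current model is the
smallest among candidates and at most ``p_enter``; an in-model covariate is
removed when its drop p-value is the largest and exceeds ``p_stay``.
Categorical covariates enter and leave as a block of reference-coded
contrasts with a multi-degree-of-freedom test.  Complete cases are, by
default, recomputed after every model change from the patients with data for
all currently selected covariates (candidate evaluation uses patients
complete for selected + candidate); a fixed complete-case set over all
candidates is available as an option.

Per-term significance and confidence intervals on the final model use Wald
statistics; the entry/stay tests use the likelihood ratio by default, with
Wald available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dosegap.metrics import round_percent

__all__ = [
    "Covariate",
    "LogisticFit",
    "SelectionThresholds",
    "SeparationError",
    "StepwiseResult",
    "TraceStep",
    "fit_logistic",
    "lr_pvalue",
    "stepwise_select",
    "table2_report",
    "covariates_from_schema",
    "significance_stars",
]

MAX_ABS_COEF = 30.0  # |log-odds| beyond this flags (quasi-)complete separation


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass(frozen=True)
class Covariate:
    """A candidate covariate and its coding.

    Binary covariates hold 0/1 values and contribute one column; categorical
    covariates hold level strings and contribute one reference-coded dummy
    per non-reference level (the first level is the reference).  A
    categorical covariate is tested as a block.
    """

    name: str
    kind: Literal["binary", "categorical"] = "binary"
    levels: tuple = (0, 1)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"covariate {self.name!r}: needs at least two levels")

    @property
    def reference(self):
        return self.levels[0]

    @property
    def term_names(self) -> list[str]:
        if self.kind == "binary":
            return [self.name]
        return [f"{self.name}[{level}]" for level in self.levels[1:]]

    def design_columns(self, data: pd.DataFrame) -> np.ndarray:
        """(n, k) float matrix of reference-coded contrasts."""
        series = data[self.name]
        cols = [(series == level).to_numpy(dtype=float) for level in self.levels[1:]]
        return np.column_stack(cols)


def covariates_from_schema(schema: dict) -> list[Covariate]:
    """Candidate list from a cohort schema (see :mod:`dosegap.io`)."""
    out = []
    for entry in schema["covariates"]:
        if entry["type"] == "binary":
            out.append(Covariate(name=entry["name"], kind="binary"))
        elif entry["type"] == "categorical":
            out.append(Covariate(name=entry["name"], kind="categorical", levels=tuple(entry["levels"])))
    return out


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model: MLE coefficients, covariance, log-likelihood."""

    term_names: tuple[str, ...]
    params: np.ndarray
    cov_params: np.ndarray
    loglik: float
    n_obs: int
    n_iter: int
    converged: bool

    def wald_p(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.cov_params))
        z = self.params / se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-term coefficients, odds ratios, Wald CIs, and p-values."""
        se = np.sqrt(np.diag(self.cov_params))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "term": list(self.term_names),
                "coef": self.params,
                "se": se,
                "odds_ratio": np.exp(self.params),
                "or_ci_low": np.exp(self.params - zcrit * se),
                "or_ci_high": np.exp(self.params + zcrit * se),
                "wald_p": self.wald_p(),
            }
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray | Sequence[int],
    X: np.ndarray,
    term_names: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares (Newton scoring).

    Converges when both the maximum absolute score and the maximum absolute
    coefficient change fall below ``tol``, or raises after ``max_iter``.
    Raises :class:`ValueError` when the outcome has a single class or the
    design is rank deficient, and :class:`SeparationError` when coefficients
    diverge (complete or quasi-complete separation).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one row per outcome")
    if X.shape[1] != len(term_names):
        raise ValueError("term_names must match the design columns")
    if y.size == 0:
        raise ValueError("no observations")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; the model is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    for iteration in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        hessian = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix during IRLS (separation or collinearity)"
            ) from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            raise SeparationError(
                "coefficients diverging (complete or quasi-complete separation)"
            )
        if np.max(np.abs(score)) < tol and np.max(np.abs(delta)) < tol:
            hessian = X.T @ (X * w[:, None])
            return LogisticFit(
                term_names=tuple(term_names),
                params=beta,
                cov_params=np.linalg.inv(hessian),
                loglik=_loglik(y, X @ beta),
                n_obs=int(y.size),
                n_iter=iteration,
                converged=True,
            )
    raise SeparationError(f"IRLS failed to converge in {max_iter} iterations")


def lr_pvalue(model_small: LogisticFit, model_large: LogisticFit) -> float:
    """Likelihood-ratio p-value for nested models fitted on the same rows.

    Identical term sets give p = 1 (zero statistic on zero degrees of
    freedom); non-nested inputs raise :class:`ValueError`.
    """
    small_terms = set(model_small.term_names)
    large_terms = set(model_large.term_names)
    if model_small.n_obs != model_large.n_obs:
        raise ValueError("models were fitted on different numbers of observations")
    if not small_terms <= large_terms:
        raise ValueError("models are not nested")
    df = len(large_terms) - len(small_terms)
    if df == 0:
        return 1.0
    statistic = max(0.0, 2.0 * (model_large.loglik - model_small.loglik))
    return float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class SelectionThresholds:
    """p-value gates for stepwise selection and final reporting."""

    p_enter: float = 0.25
    p_stay: float = 0.30
    p_significant: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_enter", "p_stay", "p_significant"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")


@dataclass(frozen=True)
class TraceStep:
    step: int
    action: Literal["enter", "remove"]
    covariate: str
    p_value: float


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of stepwise selection: the final model and how it was reached.

    ``n_complete_cases`` is the "N1" denominator — patients with data for
    all selected covariates.  ``trace`` replays to the final model.
    """

    selected: tuple[str, ...]
    covariates: tuple[Covariate, ...]
    fit: Optional[LogisticFit]
    n_complete_cases: int
    trace: tuple[TraceStep, ...]
    thresholds: SelectionThresholds

    @property
    def coefficients(self) -> dict[str, float]:
        if self.fit is None:
            return {}
        return dict(zip(self.fit.term_names, self.fit.params))

    def summary_frame(self) -> pd.DataFrame:
        if self.fit is None:
            return pd.DataFrame(
                columns=["term", "coef", "se", "odds_ratio", "or_ci_low", "or_ci_high", "wald_p"]
            )
        return self.fit.summary_frame()


def _build_design(
    data: pd.DataFrame, covariates: Sequence[Covariate]
) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["(intercept)"]
    for cov in covariates:
        blocks.append(cov.design_columns(data))
        names.extend(cov.term_names)
    return np.hstack(blocks), names


def _complete_mask(data: pd.DataFrame, covariates: Iterable[Covariate]) -> pd.Series:
    mask = pd.Series(True, index=data.index)
    for cov in covariates:
        mask &= data[cov.name].notna()
    return mask


def _fit_on(data: pd.DataFrame, outcome: str, covariates: Sequence[Covariate]) -> LogisticFit:
    X, names = _build_design(data, covariates)
    y = data[outcome].to_numpy(dtype=float)
    return fit_logistic(y, X, names)


def stepwise_select(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[Covariate],
    thresholds: SelectionThresholds | None = None,
    complete_case: Literal["iterative", "fixed"] = "iterative",
    test: Literal["lr", "wald"] = "lr",
) -> StepwiseResult:
    """Stepwise covariate selection with p-value entry/stay gates.

    Forward step: among candidates not yet in the model, add the one with
    the smallest entry p-value if it is at most ``p_enter`` (ties broken by
    candidate order).  Backward step: refit and remove the in-model
    covariate with the largest drop p-value if it exceeds ``p_stay``.
    The two alternate until neither changes the model.  Because
    ``p_enter < p_stay`` can cycle in pathological cases, a visited-model
    check plus a step limit of ``2 * len(candidates)**2 + 2`` terminates
    with the best-log-likelihood model seen.

    Deterministic given the input row order and candidate order.
    """
    thresholds = thresholds or SelectionThresholds()
    candidates = list(candidates)
    if data.empty:
        raise ValueError("no observations")
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} missing")
    for cov in candidates:
        if cov.name not in data.columns:
            raise ValueError(f"candidate column {cov.name!r} missing")

    fixed_mask = _complete_mask(data, candidates) if complete_case == "fixed" else None

    def rows_for(covs: Sequence[Covariate]) -> pd.DataFrame:
        mask = fixed_mask if fixed_mask is not None else _complete_mask(data, covs)
        return data.loc[mask]

    def entry_p(selected: list[Covariate], cand: Covariate) -> float | None:
        rows = rows_for([*selected, cand])
        if rows.empty:
            return None
        try:
            large = _fit_on(rows, outcome, [*selected, cand])
            if test == "lr":
                small = _fit_on(rows, outcome, selected)
                return lr_pvalue(small, large)
            ps = [
                p for name, p in zip(large.term_names, large.wald_p())
                if name in cand.term_names
            ]
            return min(ps)
        except (ValueError, SeparationError):
            return None  # degenerate on these rows: skip the candidate

    def drop_p(selected: list[Covariate], cov: Covariate, rows: pd.DataFrame, full: LogisticFit) -> float:
        if test == "lr":
            small = _fit_on(rows, outcome, [c for c in selected if c is not cov])
            return lr_pvalue(small, full)
        ps = [p for name, p in zip(full.term_names, full.wald_p()) if name in cov.term_names]
        return min(ps)

    selected: list[Covariate] = []
    trace: list[TraceStep] = []
    visited: set[frozenset[str]] = set()
    seen_models: dict[frozenset[str], tuple[float, tuple[str, ...]]] = {}
    step = 0
    max_steps = 2 * max(1, len(candidates)) ** 2 + 2

    def record_model() -> None:
        key = frozenset(c.name for c in selected)
        rows = rows_for(selected)
        if rows.empty:
            return
        try:
            fit = _fit_on(rows, outcome, selected)
        except (ValueError, SeparationError):
            return
        seen_models[key] = (fit.loglik, tuple(c.name for c in selected))

    record_model()
    while step < max_steps:
        changed = False

        best_cand, best_p = None, None
        for cand in candidates:
            if any(c.name == cand.name for c in selected):
                continue
            p = entry_p(selected, cand)
            if p is None:
                continue
            if best_p is None or p < best_p - 1e-15:
                best_cand, best_p = cand, p
        if best_cand is not None and best_p <= thresholds.p_enter:
            step += 1
            selected.append(best_cand)
            trace.append(TraceStep(step, "enter", best_cand.name, best_p))
            changed = True
            record_model()

        if selected:
            rows = rows_for(selected)
            try:
                full = _fit_on(rows, outcome, selected)
                worst_cov, worst_p = None, None
                for cov in selected:
                    p = drop_p(selected, cov, rows, full)
                    if worst_p is None or p > worst_p + 1e-15:
                        worst_cov, worst_p = cov, p
                if worst_cov is not None and worst_p > thresholds.p_stay:
                    step += 1
                    selected.remove(worst_cov)
                    trace.append(TraceStep(step, "remove", worst_cov.name, worst_p))
                    changed = True
                    record_model()
            except (ValueError, SeparationError):
                pass  # keep the model as-is if the refit degenerates

        key = frozenset(c.name for c in selected)
        if not changed:
            break
        if key in visited:
            # cycle: fall back to the best log-likelihood model seen
            if seen_models:
                _, best_names = max(seen_models.values(), key=lambda t: t[0])
                by_name = {c.name: c for c in candidates}
                selected = [by_name[name] for name in best_names]
            break
        visited.add(key)

    rows = rows_for(selected)
    if rows.empty:
        raise ValueError("no complete cases for the selected covariates")
    fit = _fit_on(rows, outcome, selected)
    return StepwiseResult(
        selected=tuple(c.name for c in selected),
        covariates=tuple(selected),
        fit=fit,
        n_complete_cases=len(rows),
        trace=tuple(trace),
        thresholds=thresholds,
    )


def significance_stars(p: float) -> str:
    """Star annotation: ``*`` p<=0.05, ``**`` p<=0.01, ``***`` p<=0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def table2_report(
    data: pd.DataFrame,
    outcome: str,
    result: StepwiseResult,
) -> pd.DataFrame:
    """Per-level persistence breakdown for the selected covariates.

    For every level of every selected covariate: the number of persistent
    patients over the complete-case denominator ("N1") within that level,
    the percentage (one decimal), and significance stars from the final
    model's Wald p-value for the level's contrast.  Reference levels carry
    no star.
    """
    if result.fit is None:
        raise ValueError("a fitted result is required")
    rows_mask = _complete_mask(data, result.covariates)
    rows = data.loc[rows_mask]
    wald = dict(zip(result.fit.term_names, result.fit.wald_p()))

    records = []
    for cov in result.covariates:
        for level in cov.levels:
            in_level = rows[rows[cov.name] == level]
            if in_level.empty and level not in set(rows[cov.name].dropna().unique()):
                raise ValueError(f"level {level!r} of {cov.name!r} absent from the data")
            n1 = len(in_level)
            n_persist = int(in_level[outcome].sum())
            is_reference = level == cov.reference
            term = None if is_reference else (
                cov.name if cov.kind == "binary" else f"{cov.name}[{level}]"
            )
            p = None if term is None else float(wald[term])
            records.append(
                {
                    "covariate": cov.name,
                    "level": str(level),
                    "is_reference": is_reference,
                    "n_persistent": n_persist,
                    "n1": n1,
                    "percent": round_percent(100.0 * n_persist / n1) if n1 else float("nan"),
                    "wald_p": p,
                    "stars": "" if p is None else significance_stars(p),
                }
            )
    return pd.DataFrame.from_records(records)
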