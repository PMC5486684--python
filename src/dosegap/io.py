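"""Cohort file formats: delimited injections/covariates plus a JSON schema.

Three plain-text files describe a cohort:

* ``injections.csv`` — ``patient_id, injection_seq, injection_date`` with
  1-based sequence numbers and ISO-8601 dates; one row per injection.
* ``covariates.csv`` — one row per patient; ``patient_id``, ``stratum`` and
  ``observation_end_day`` metadata columns followed by one column per
  covariate (empty cell = missing).
* ``schema.json`` — declares each covariate's type and category levels plus
  the calendar epoch used to serialise day offsets.

Internally all dates are integer day offsets from the patient's first
injection; the calendar appears only here.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from dosegap.metrics import InjectionHistory
from dosegap.synthetic import PatientCovariates, SimulationConfig, SyntheticCohort

__all__ = [
    "CohortPaths",
    "CohortValidationError",
    "write_cohort",
    "read_cohort",
    "validate_cohort_files",
    "schema_from_config",
]

DEFAULT_EPOCH = dt.date(2011, 1, 1)
META_COLUMNS = ("patient_id", "stratum", "observation_end_day")


@dataclass(frozen=True)
class CohortPaths:
    """Locations of the three cohort files; `in_dir` uses default names."""

    injections: Path
    covariates: Path
    schema: Path

    @classmethod
    def in_dir(cls, directory: Path | str) -> "CohortPaths":
        d = Path(directory)
        return cls(d / "injections.csv", d / "covariates.csv", d / "schema.json")


class CohortValidationError(ValueError):
    """Raised on malformed cohort files; carries itemised violations."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations) if violations else "invalid cohort files")


def schema_from_config(config: SimulationConfig) -> dict[str, Any]:
    covs = []
    for spec in config.covariate_specs:
        entry: dict[str, Any] = {"name": spec.name, "type": spec.type}
        if spec.type == "categorical":
            entry["levels"] = list(spec.levels or [])
        covs.append(entry)
    return {
        "epoch": DEFAULT_EPOCH.isoformat(),
        "meta_columns": list(META_COLUMNS),
        "covariates": covs,
    }


def write_cohort(
    cohort: SyntheticCohort,
    paths: CohortPaths | Path | str,
    schema: Optional[dict[str, Any]] = None,
) -> CohortPaths:
    """Write a cohort to the three-file format; returns the paths used.

    Output is deterministic: rows are ordered by patient id and sequence, so
    identical cohorts produce byte-identical files.
    """
    if not isinstance(paths, CohortPaths):
        Path(paths).mkdir(parents=True, exist_ok=True)
        paths = CohortPaths.in_dir(paths)
    if schema is None:
        if cohort.truth is None:
            raise ValueError("a schema is required when the cohort carries no truth config")
        schema = schema_from_config(cohort.truth)
    epoch = dt.date.fromisoformat(schema.get("epoch", DEFAULT_EPOCH.isoformat()))

    inj_rows = []
    for history in cohort.histories:
        for seq, day in enumerate(history.injection_days, start=1):
            inj_rows.append(
                {
                    "patient_id": history.patient_id,
                    "injection_seq": seq,
                    "injection_date": (epoch + dt.timedelta(days=int(day))).isoformat(),
                }
            )
    pd.DataFrame(inj_rows).to_csv(paths.injections, index=False, lineterminator="\n")

    cov_names = [c["name"] for c in schema["covariates"]]
    cov_rows = []
    for history, cov in zip(cohort.histories, cohort.covariates):
        row: dict[str, Any] = {
            "patient_id": cov.patient_id,
            "stratum": cov.stratum,
            "observation_end_day": history.observation_end_day,
        }
        for name in cov_names:
            value = cov.values.get(name)
            row[name] = "" if value is None else value
        cov_rows.append(row)
    pd.DataFrame(cov_rows).to_csv(paths.covariates, index=False, lineterminator="\n")

    with open(paths.schema, "w") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _load_schema(path: Path) -> dict[str, Any]:
    with open(path) as fh:
        schema = json.load(fh)
    if "covariates" not in schema or not isinstance(schema["covariates"], list):
        raise CohortValidationError([f"{path}: schema must declare a 'covariates' list"])
    return schema


def validate_cohort_files(paths: CohortPaths) -> list[str]:
    """Check the three files and return an itemised list of violations.

    Detects unordered or duplicate injection dates, bad sequence numbers,
    duplicate patient ids, unknown category levels, out-of-range scores
    (``mmas8_score`` must lie in [0, 8]), and injection/covariate id
    mismatches.  An empty list means the files are well formed.
    """
    violations: list[str] = []
    try:
        schema = _load_schema(paths.schema)
    except (OSError, json.JSONDecodeError) as exc:
        return [f"{paths.schema}: unreadable schema ({exc})"]
    except CohortValidationError as exc:
        return list(exc.violations)

    try:
        inj = pd.read_csv(paths.injections, dtype={"patient_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        return [f"{paths.injections}: unreadable ({exc})"]
    for col in ("patient_id", "injection_seq", "injection_date"):
        if col not in inj.columns:
            violations.append(f"{paths.injections}: missing column {col!r}")
    if violations:
        return violations

    try:
        dates = pd.to_datetime(inj["injection_date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        return [f"{paths.injections}: unparseable injection_date ({exc})"]
    inj = inj.assign(_date=dates)

    for pid, group in inj.groupby("patient_id", sort=True):
        group = group.sort_values("injection_seq")
        seqs = group["injection_seq"].tolist()
        if seqs != list(range(1, len(seqs) + 1)):
            violations.append(f"{paths.injections}: patient {pid}: injection_seq not 1..n ({seqs})")
        day_list = group["_date"].tolist()
        for a, b, seq in zip(day_list, day_list[1:], seqs[1:]):
            if b <= a:
                violations.append(
                    f"{paths.injections}: patient {pid}: injection {seq} dated "
                    f"{b.date()} not after injection {seq - 1} ({a.date()})"
                )

    try:
        cov = pd.read_csv(paths.covariates, dtype={"patient_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        return violations + [f"{paths.covariates}: unreadable ({exc})"]
    for col in META_COLUMNS:
        if col not in cov.columns:
            violations.append(f"{paths.covariates}: missing column {col!r}")
    if any(v.startswith(str(paths.covariates)) for v in violations):
        return violations

    dup = cov["patient_id"][cov["patient_id"].duplicated()]
    for pid in dup.unique():
        violations.append(f"{paths.covariates}: duplicate patient id {pid!r}")

    inj_ids = set(inj["patient_id"])
    cov_ids = set(cov["patient_id"])
    for pid in sorted(inj_ids - cov_ids):
        violations.append(f"{paths.covariates}: patient {pid!r} has injections but no covariate row")
    for pid in sorted(cov_ids - inj_ids):
        violations.append(f"{paths.injections}: patient {pid!r} has covariates but no injections")

    for entry in schema["covariates"]:
        name = entry["name"]
        if name not in cov.columns:
            violations.append(f"{paths.covariates}: missing covariate column {name!r}")
            continue
        series = cov[name]
        if entry["type"] == "categorical":
            levels = set(entry.get("levels", []))
            observed = set(series.dropna().astype(str))
            for bad in sorted(observed - levels):
                violations.append(
                    f"{paths.covariates}: covariate {name!r}: level {bad!r} not among "
                    f"declared levels {sorted(levels)}"
                )
        elif entry["type"] == "binary":
            observed = set(series.dropna().astype(str))
            for bad in sorted(observed - {"0", "1", "0.0", "1.0"}):
                violations.append(f"{paths.covariates}: covariate {name!r}: non-binary value {bad!r}")
        elif entry["type"] == "number":
            numeric = pd.to_numeric(series, errors="coerce")
            for pid in cov.loc[series.notna() & numeric.isna(), "patient_id"]:
                violations.append(f"{paths.covariates}: covariate {name!r}: non-numeric value for {pid}")
            lo, hi = entry.get("min"), entry.get("max")
            for pid, val in zip(cov["patient_id"], numeric):
                if pd.isna(val):
                    continue
                if (lo is not None and val < lo) or (hi is not None and val > hi):
                    violations.append(
                        f"{paths.covariates}: covariate {name!r}: value {val} for {pid} "
                        f"outside [{lo}, {hi}]"
                    )

    if "mmas8_score" in cov.columns and not any(
        e["name"] == "mmas8_score" for e in schema["covariates"]
    ):
        numeric = pd.to_numeric(cov["mmas8_score"], errors="coerce")
        for pid, val in zip(cov["patient_id"], numeric):
            if pd.notna(val) and not 0 <= val <= 8:
                violations.append(
                    f"{paths.covariates}: mmas8_score {val} for {pid} outside [0, 8]"
                )

    return violations


def read_cohort(paths: CohortPaths | Path | str) -> SyntheticCohort:
    """Read a cohort back from the three-file format.

    Raises :class:`CohortValidationError` with itemised violations if the
    files are malformed.  The returned cohort carries no truth config.
    """
    if not isinstance(paths, CohortPaths):
        paths = CohortPaths.in_dir(paths)
    violations = validate_cohort_files(paths)
    if violations:
        raise CohortValidationError(violations)

    schema = _load_schema(paths.schema)
    inj = pd.read_csv(paths.injections, dtype={"patient_id": str})
    inj = inj.assign(_date=pd.to_datetime(inj["injection_date"], format="%Y-%m-%d").dt.date)
    cov = pd.read_csv(paths.covariates, dtype={"patient_id": str})

    histories: list[InjectionHistory] = []
    covariates: list[PatientCovariates] = []
    by_patient = {pid: g.sort_values("injection_seq") for pid, g in inj.groupby("patient_id")}
    for _, row in cov.sort_values("patient_id").iterrows():
        pid = row["patient_id"]
        group = by_patient[pid]
        first = group["_date"].iloc[0]
        days = tuple(int((d - first).days) for d in group["_date"])
        histories.append(
            InjectionHistory(
                patient_id=pid,
                injection_days=days,
                observation_end_day=int(row["observation_end_day"]),
            )
        )
        values: dict[str, Any] = {}
        for entry in schema["covariates"]:
            name = entry["name"]
            raw = row.get(name)
            if pd.isna(raw):
                values[name] = None
            elif entry["type"] == "binary":
                values[name] = int(float(raw))
            elif entry["type"] == "number":
                values[name] = float(raw)
            else:
                values[name] = str(raw)
        covariates.append(PatientCovariates(patient_id=pid, stratum=str(row["stratum"]), values=values))

    return SyntheticCohort(histories=tuple(histories), covariates=tuple(covariates), truth=None)
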