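# dosegap

Medication-taking analysis for 6-monthly injectable therapy: gap-window
persistence/adherence classification, the medication coverage ratio (MCR),
sensitivity-window grids, stratified proportion summaries with 95% CIs, and
stepwise multivariable logistic regression of baseline factors associated
with 24-month persistence — plus a synthetic-cohort simulator so every stage
is testable without patient data.

## Concepts

* **Persistence** — the next injection arrives within the nominal 183-day
  interval plus an allowance (default 8 weeks); 24-month persistence
  requires four injections with every consecutive gap inside the window.
* **Adherence** — every consecutive gap lies within 183 ± a tolerance
  (default 4 weeks); a stricter criterion, so adherence ≤ persistence.
* **MCR** — each injection covers 183 days; the MCR is the percentage of
  observed time covered by the union of those intervals (overlaps from early
  re-injection are never double-counted).
* **Stepwise selection** — covariates enter the per-stratum logistic model
  of persistence when their likelihood-ratio p-value is ≤ 0.25 and stay
  while it is ≤ 0.3; per-term significance uses Wald tests at 0.05.

## Command line

```bash
# simulate a cohort (injections.csv, covariates.csv, schema.json)
dosegap simulate --config sim.json --out-dir cohort/ --seed 1

# per-patient outcomes, summaries, and the sensitivity grid
dosegap metrics --injections cohort/injections.csv \
    --covariates cohort/covariates.csv --out metrics/

# per-stratum stepwise model of 24-month persistence
dosegap stepwise --outcomes metrics/outcomes.csv \
    --covariates cohort/covariates.csv --schema cohort/schema.json \
    --stratum Germany --out model/

# everything in one run (writes a manifest with config hash + seed)
dosegap run --config run.json --seed 1

# validate input files (exit code 2 + itemized violations on failure)
dosegap validate --injections cohort/injections.csv \
    --covariates cohort/covariates.csv
```

A minimal run config:

```json
{
  "simulate": {"n_patients": 1500, "seed": 1,
               "strata": [["Germany", 0.39], ["Austria", 0.20],
                           ["Greece", 0.21], ["Belgium", 0.20]]},
  "out_dir": "bundle/"
}
```

`dosegap.synthetic.default_study_config()` builds a full study-shaped
simulation config (four country strata, published-range covariate
prevalences, covariate-dependent discontinuation).

## Python API

```python
from dosegap import (
    InjectionHistory, WindowPolicy, classify_persistence, compute_mcr,
    summarize_proportion, generate_cohort, stepwise_select,
)

h = InjectionHistory("p1", (0, 183, 370, 560), observation_end_day=731)
classify_persistence(h)            # True: every gap <= 183 + 56
compute_mcr(h)                     # % of 731 days covered
summarize_proportion(70, 101)      # 69.3% with Wilson 95% CI
```

## Layout

* `src/dosegap/metrics.py` — histories, window policies, classification,
  MCR, proportion summaries, sensitivity grid, MMAS-8 categorization.
* `src/dosegap/synthetic.py` — simulation configs and the cohort generator.
* `src/dosegap/io.py` — delimited injections/covariates files + JSON schema.
* `src/dosegap/model.py` — IRLS logistic regression, LR tests, stepwise
  selection, per-level breakdown tables.
* `src/dosegap/pipeline.py` / `cli.py` — orchestration and the CLI.
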