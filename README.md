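# shockbias

Monte-Carlo audit of the *highest-class composite* allocation used when
hypovolemic-shock classifications are compared head-to-head. The package
simulates trauma cohorts with a Gaussian copula (heart rate, systolic blood
pressure, Glasgow Coma Scale, base deficit, transfusion volume), classifies
each patient into shock classes I–IV per parameter, forms a maximum composite,
and measures how the composite-vs-singleton comparison systematically favors
whichever parameter is left outside the composite — even when every predictor
shares the same underlying rank correlation with the outcome.

## What it does

Four scenarios run end to end:

| scenario | composite | singleton | predictor–transfusion Spearman targets |
|---|---|---|---|
| `equal` | hr, sbp, gcs | bd | all 0.55 |
| `unequal` | hr, sbp, gcs | bd | 0.8 (hr/sbp/gcs), 0.3 (bd) |
| `swap-equal` | bd, sbp, gcs | hr | all 0.55 |
| `swap-unequal` | bd, sbp, gcs | hr | 0.8 (hr/sbp/gcs), 0.3 (bd) |

Per scenario the report contains: per-class transfusion comparisons between
the singleton and composite schemes (pooled two-sample t-tests — the method
under critique, reproduced deliberately including its overlapping-group
independence violation), post-processing Spearman correlations of every
predictor with transfusion, and the fraction of patients whose hr/sbp/gcs
classes all agree.

The shipped marginal distribution parameters are **documented placeholders**
(physiologically plausible; the originally estimated values are configuration
inputs). Every run that uses them carries a warning into all output files.
Replace them through the YAML config — no code change needed.

## CLI

```sh
# all four scenarios with default (placeholder) parameters
shockbias run --seed 1 --out out/

# with a config file; figures optional
shockbias run --config examples/config.yaml --scenario equal --out out/ --figures

# recompute summary.json / comparisons.csv from saved cohort tables
shockbias replay out/
```

Outputs per run: `manifest.json` (provenance, seeds, warnings — written before
any statistics), `config.yaml`, `summary.json`, `comparisons.csv`, and per
scenario `cohort.csv`, `classes.csv`, `scenario.json` (plus optional
histogram / class-mean figures). Replays are byte-identical. Exit codes:
0 success, 2 config error, 3 degenerate-statistics-only run.

Minimal config (`examples/config.yaml` shows the full schema):

```yaml
seed: 1
n: 16305
truncation: clip          # or: quantile (rank-preserving inverse CDF)
correlation: {base: 0.55, strong: 0.8, weak: 0.3}
marginals:
  hr: {location: 100.0, scale: 28.0, lower_bound: 30.0, upper_bound: 220.0}
```

## Python API

```python
from shockbias import MasterConfig, run_all_scenarios

summaries = run_all_scenarios(MasterConfig(seed=1))
summaries["equal"].postprocessing_spearman   # {'hr': 0.53, 'sbp': -0.54, ...}
summaries["equal"].joint_class_fraction      # ~0.14
```

Determinism: everything is a pure function of the master seed. Each scenario
seed derives from the master seed by a fixed counter scheme (the `swap-*`
scenarios intentionally share the cohort draw of their non-swap counterpart);
within a scenario, the copula stream and the GCS-15 class-split stream are
independent substreams.

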