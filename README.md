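# oxival

A validation pipeline for wearable pulse oximeters, comparing device SpO₂
streams against arterial-blood reference saturation (SaO₂):

- **`session_model`** — domain types (`SpO2Stream`, `ReferenceSample`,
  `TaskAnnotation`, `Session`, `StudyDataset`) and bit-exact plain-text
  readers/writers for the session directory format.
- **`synthetic_data`** — a study-session simulator: movement phase (at-rest
  window + six motion tasks at a near-100% baseline with a transient
  sit-to-stand desaturation dip) and a hypoxia phase stepping through stable
  plateaus at 100/95/90/87/85/83/80% targets; per-device systematic bias,
  Gaussian scatter, vendor-style smoothing, task-specific motion artifacts and
  stream dropout; arterial samples at task ends and plateau midpoints.
- **`windowing`** — windowed-median SpO₂/SaO₂ pairing: `[stop − 40 s, stop)`
  for motion tasks, `[t − 35 s, t + 5 s]` around hypoxia references, with a
  configurable minimum of valid samples per window (default 20/40) and
  per-device emitted/dropped accounting.
- **`accuracy_metrics`** — RMSE, mean bias, mean |bias|, precision (residual
  SD around the SpO₂-on-SaO₂ least-squares line), percentile-bootstrap CIs
  (10,000 reps by default, with a cluster-by-session option), Bland-Altman
  limits of agreement, and the ISO 80601-2-61-style checks (RMSE ≤ 4% with CI
  upper bound ≤ 8%; ≥ 200 points from ≥ 10 subjects balanced over 70–100%).
- **`group_comparison`** — one-way ANOVA + Tukey-Kramer post hoc, Levene
  (mean- or median-centered), and a paired Wilcoxon signed-rank test with a
  tie-aware exact null distribution for n ≤ 25.
- **`hypoxemia_detection`** — error matrix for SaO₂ < 90% detection at an
  SpO₂ < cutoff rule, sensitivity/specificity/PPV/NPV/accuracy with
  class-stratified bootstrap CIs, ROC sweep over observed scores, trapezoidal
  AUROC (= rank concordance), and the Youden-optimal operating cut-off.
- **`cli`** — the `oxival` command (subcommands below) and the
  `run_pipeline` orchestrator with a reproducibility manifest.

## CLI

```sh
oxival simulate --config sim.yaml --out dataset/ --seed 1
oxival match    --in dataset/ --phase hypoxia --out pairs.csv
oxival accuracy --pairs pairs.csv --by device_id,stratum --reps 10000 --seed 2 --out table.csv
oxival compare  --pairs pairs.csv --metric bias --by stratum --out compare.csv
oxival detect   --pairs pairs.csv --cutoff 90 --reps 10000 --seed 3 --out detection.csv
oxival run      --config run.yaml --out results/
```

`run` drives simulate → match → accuracy/compare/detect end to end from one
YAML file (an explicit `seed` is required; rerunning a manifest reproduces
byte-identical numeric outputs). Example:

```yaml
seed: 1
reps: 10000
cutoff: 90.0
simulation:
  n_participants: 33
  devices:
    - {device_id: finger-1, systematic_bias: -1.9, scatter_sd: 2.7}
    - {device_id: finger-2, systematic_bias: 0.5, scatter_sd: 2.6}
```

## Session directory format

All files are comma-separated UTF-8 with a header row; empty field = missing
value; times are seconds from session start.

| file | columns | units |
| --- | --- | --- |
| `streams/<device_id>.csv` | `t,spo2` | s, % (blank = dropout sample) |
| `annotations.csv` | `label,start,stop` | task name, s, s |
| `references.csv` | `t,sao2,phase,label,kind` | s, %, movement/hypoxia, task or target level, end-of-task/mid-task/plateau |
| `session.yaml` | `session_id`, `demographics` | pass-through participant descriptors |

A study dataset adds `study.yaml` (device roster + session directory names).

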