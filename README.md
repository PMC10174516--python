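# gasselect

Metaheuristic wrapper feature selection for 4-class tabular outcome
prediction, built around a Henry's-law gas-solubility optimizer paired with an
Aquila-style optimizer, a hybrid RF-SVM "double classifier", and a synthetic
neurosurgical-style data generator with planted informative features.

## What's inside

| Module | Purpose |
| --- | --- |
| `gasselect.data_model` | `Dataset` container, CSV I/O, declarative encoding (ordinal / one-hot / numeric + min-max to a domain range), stratified 80/20 splitting |
| `gasselect.synthetic_data` | Seeded generator: class-conditional Gaussian informative columns + pure-noise columns, ground-truth sidecar for recovery scoring |
| `gasselect.hgso_core` | Gas-solubility optimization engine: clustered Henry coefficients, temperature-driven solubility updates, worst-agent escape, diversity / exploration-exploitation diagnostics |
| `gasselect.aqo_core` | Aquila-style optimizer (exploration ≤ 2/3 of the budget, then exploitation) and the sequential hybrid hand-off into the gas engine |
| `gasselect.feature_selection` | Binarization at the 0.5 threshold, wrapper fitness `λ·error + (1−λ)·|mask|/D`, end-to-end `select_features` |
| `gasselect.classifiers` | knn / rf / c45 / ann / svm plus the soft-voting RF-SVM ensemble behind one fit/predict contract |
| `gasselect.evaluation` | Confusion matrices, binary + macro metrics, exact/approximate Wilcoxon signed-rank |
| `gasselect.experiment` + `gasselect.cli` | Config-driven grid runner (models × pop sizes × with/without selection), summaries, paired comparison, report export |

## CLI

```bash
# synthetic dataset + ground-truth sidecar
gas-select generate --class-counts 800,700,850,650 --n-informative 12 \
    --n-noise 25 --effect-size 2.0 --seed 0 --out data.csv

# wrapper feature selection on a CSV (hgso | aqo | hybrid)
gas-select select --data data.csv --optimizer hgso --pop-size 30 \
    --epochs 50 --seed 0 --out selection.json

# full experiment grid from a YAML config (presets: src/gasselect/configs/)
gas-select run --config src/gasselect/configs/table3.yaml --seed 1 --out results/

# paired Wilcoxon between two models in a results table
gas-select compare --results results/results.csv --model-a rf_svm --model-b svm

# re-export summaries from an existing results CSV
gas-select report --results results/results.csv --out report/
```

Experiment configs are YAML (see `src/gasselect/configs/table3.yaml` for the
schema): runs, epochs, pop sizes, model list, with/without-selection flags,
optimizer strategy, λ, and a data source (CSV path or generator spec).
Reports include results/summary CSVs, per-run convergence traces, and a
manifest with SHA-256 checksums; re-running the same config reproduces the
results CSV byte for byte.

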